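"""Seeded synthetic case-control cohort generator.

Emulates the statistical shape of a Medicare-style 1:1 matched
case-control extract of readmitted patients: sparse binary comorbidity
indicators, planted patient-comorbidity block (bicluster) structure among
cases, and planted pairwise interaction effects of comorbidities on the
readmission outcome.

Mechanism
---------
Two rejection-sampled candidate streams share one seeded generator,
consumed in a fixed documented order (block assignment -> presence ->
outcome draw), so identical configs give bit-identical cohorts:

* *case candidates*: each is assigned to a planted block with the
  configured fractions (remainder: no block); comorbidity presence is
  Bernoulli(p_in) on the block's comorbidities and Bernoulli(p_out)
  elsewhere.  The candidate becomes a case when a Bernoulli draw with
  probability ``sigmoid(eta)`` comes up 1, where
  ``eta = intercept + main_effects . x + sum_{i<j} log_or[i,j] x_i x_j``.
* *control candidates*: presence is Bernoulli(p_out) everywhere
  (matched controls share only the background comorbidity process);
  accepted when the same Bernoulli draw comes up 0.

With exposure defined as "has both members of a planted pair" and no
other effects, the population odds ratio of the outcome for that
exposure is exactly ``exp(log_or[i,j])``, so planted effects are
recoverable by a plain 2x2 cross-product ratio downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortMatrix
from .errors import ComputationError, DataValidationError

__all__ = [
    "Block",
    "SynthConfig",
    "SyntheticTruth",
    "generate_cohort",
    "medicare_like",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class Block:
    """A planted bicluster: a comorbidity subset enriched in a case stratum.

    ``comorbidities`` are column indices; ``patient_fraction`` is the share
    of case candidates assigned to the block; ``p_in`` the within-block
    presence probability.
    """

    comorbidities: tuple[int, ...]
    patient_fraction: float
    p_in: float


@dataclass
class SynthConfig:
    """Full specification of one synthetic cohort draw.

    ``planted_log_or`` is a symmetric K x K matrix of pairwise interaction
    effects (log odds-ratio scale) on the outcome; ``main_effects`` a
    length-K vector; both default to zero.
    """

    n_cases: int
    comorbidity_names: list[str]
    n_controls: int | None = None
    block_spec: list[Block] = field(default_factory=list)
    p_out: float = 0.0436
    planted_log_or: np.ndarray | None = None
    main_effects: np.ndarray | None = None
    intercept: float = 0.0
    seed: int = 0
    max_draw_factor: int = 100
    generator: str = "numpy-pcg64"  # algorithm behind the seeded stream

    def __post_init__(self) -> None:
        k = len(self.comorbidity_names)
        if self.n_controls is None:
            self.n_controls = self.n_cases  # 1:1 matched design
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise DataValidationError("n_cases and n_controls must be positive")
        if k < 2 or len(set(self.comorbidity_names)) != k:
            raise DataValidationError("need >= 2 distinct comorbidity names")
        if self.planted_log_or is None:
            self.planted_log_or = np.zeros((k, k))
        self.planted_log_or = np.asarray(self.planted_log_or, dtype=float)
        if self.planted_log_or.shape != (k, k):
            raise DataValidationError("planted_log_or must be K x K")
        if not np.allclose(self.planted_log_or, self.planted_log_or.T):
            raise DataValidationError("planted_log_or must be symmetric")
        if np.abs(np.diag(self.planted_log_or)).max(initial=0.0) > 0:
            raise DataValidationError("planted_log_or diagonal must be zero")
        if self.main_effects is None:
            self.main_effects = np.zeros(k)
        self.main_effects = np.asarray(self.main_effects, dtype=float)
        if self.main_effects.shape != (k,):
            raise DataValidationError("main_effects must have length K")
        if not 0 <= self.p_out < 1:
            raise DataValidationError("p_out must be in [0, 1)")
        self.block_spec = [
            b if isinstance(b, Block) else Block(tuple(b[0]), b[1], b[2])
            for b in self.block_spec
        ]
        total_frac = sum(b.patient_fraction for b in self.block_spec)
        if total_frac > 1 + 1e-12:
            raise DataValidationError("block patient fractions sum to > 1")
        seen: set[int] = set()
        for b in self.block_spec:
            if not self.p_out < b.p_in <= 1:
                raise DataValidationError("blocks require p_out < p_in <= 1")
            if any(i < 0 or i >= k for i in b.comorbidities):
                raise DataValidationError("block comorbidity index out of range")
            if seen & set(b.comorbidities):
                raise DataValidationError("blocks must not share comorbidities")
            seen |= set(b.comorbidities)
        if self.seed < 0:
            raise DataValidationError("seed must be non-negative")

    @property
    def n_comorbidities(self) -> int:
        return len(self.comorbidity_names)


@dataclass
class SyntheticTruth:
    """Planted structure echoed alongside a generated cohort.

    Block indices are positions in ``config.block_spec``; ``None`` marks
    patients/comorbidities outside every block.
    """

    true_block_of_patient: dict[str, int | None]
    true_block_of_comorbidity: dict[str, int | None]
    planted_log_or: np.ndarray
    config: SynthConfig

    def planted_pairs(self) -> list[tuple[str, str]]:
        """Comorbidity-name pairs with a nonzero planted interaction."""
        names = self.config.comorbidity_names
        k = len(names)
        return [
            (names[i], names[j])
            for i in range(k)
            for j in range(i + 1, k)
            if self.planted_log_or[i, j] != 0.0
        ]


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _eta(X: np.ndarray, config: SynthConfig) -> np.ndarray:
    # 0.5 * x' L x gives sum_{i<j} L_ij x_i x_j for symmetric zero-diag L
    inter = 0.5 * np.einsum("nk,kl,nl->n", X, config.planted_log_or, X)
    return config.intercept + X @ config.main_effects + inter


def _draw_stream(
    config: SynthConfig,
    rng: np.random.Generator,
    n_wanted: int,
    want_case: bool,
    max_draws: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Rejection-sample one outcome class; returns (X, block, draws used)."""
    k = config.n_comorbidities
    fracs = np.array([b.patient_fraction for b in config.block_spec])
    cum = np.cumsum(fracs)
    kept_X: list[np.ndarray] = []
    kept_block: list[np.ndarray] = []
    n_kept = 0
    drawn = 0
    batch = max(1024, n_wanted)
    while n_kept < n_wanted:
        if drawn >= max_draws:
            raise ComputationError(
                f"could not reach {n_wanted} "
                f"{'cases' if want_case else 'controls'} within "
                f"{max_draws} candidate draws (short by {n_wanted - n_kept})"
            )
        nb = min(batch, max_draws - drawn)
        drawn += nb
        # 1. block assignment (cases only carry planted blocks)
        if want_case and len(config.block_spec) > 0:
            u = rng.random(nb)
            block = np.searchsorted(cum, u, side="right")
            block[u >= cum[-1]] = -1 if cum[-1] < 1 else len(fracs) - 1
            block[block >= len(fracs)] = -1
        else:
            block = np.full(nb, -1, dtype=int)
            if want_case:
                rng.random(nb)  # keep stream layout identical with/without blocks
        # 2. comorbidity presence
        probs = np.full((nb, k), config.p_out)
        for bi, b in enumerate(config.block_spec):
            members = block == bi
            if members.any():
                probs[np.ix_(members, np.array(b.comorbidities))] = b.p_in
        X = (rng.random((nb, k)) < probs).astype(np.int8)
        # 3. outcome draw from the logistic model
        p = _sigmoid(_eta(X, config))
        y = rng.random(nb) < p
        keep = y if want_case else ~y
        kept_X.append(X[keep])
        kept_block.append(block[keep])
        n_kept += int(keep.sum())
    X = np.concatenate(kept_X)[:n_wanted]
    block = np.concatenate(kept_block)[:n_wanted]
    return X, block, drawn


def generate_cohort(config: SynthConfig) -> tuple[CohortMatrix, SyntheticTruth]:
    """Generate one seeded cohort plus its planted-structure sidecar.

    Cases come first in row order, then controls.  Same config (including
    seed) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    max_total = config.max_draw_factor * (config.n_cases + config.n_controls)
    X_case, block_case, used = _draw_stream(
        config, rng, config.n_cases, want_case=True, max_draws=max_total
    )
    X_ctrl, _, _ = _draw_stream(
        config, rng, config.n_controls, want_case=False,
        max_draws=max_total - used,
    )
    n = config.n_cases + config.n_controls
    width = max(6, len(str(n)))
    ids = np.array([f"P{i:0{width}d}" for i in range(n)], dtype=object)
    outcome = np.concatenate(
        [np.ones(config.n_cases, dtype=np.int8),
         np.zeros(config.n_controls, dtype=np.int8)]
    )
    X = np.concatenate([X_case, X_ctrl])
    cohort = CohortMatrix(ids, outcome, X, list(config.comorbidity_names))
    block_of_patient: dict[str, int | None] = {}
    for pid, b in zip(ids[: config.n_cases], block_case):
        block_of_patient[pid] = int(b) if b >= 0 else None
    for pid in ids[config.n_cases:]:
        block_of_patient[pid] = None
    block_of_com: dict[str, int | None] = {
        name: None for name in config.comorbidity_names
    }
    for bi, b in enumerate(config.block_spec):
        for ci in b.comorbidities:
            block_of_com[config.comorbidity_names[ci]] = bi
    truth = SyntheticTruth(
        block_of_patient, block_of_com, config.planted_log_or.copy(), config
    )
    return cohort, truth


def medicare_like(
    n_cases: int = 2000,
    seed: int = 0,
    n_blocks: int = 7,
    p_in: float = 0.3,
    block_fraction: float = 0.05,
    pair_log_or: float = math.log(2.0),
) -> SynthConfig:
    """Preset emulating the marginal shape of the Medicare extract.

    37 comorbidity indicators with background prevalence 0.0436, which
    gives a ~19% zero-comorbidity rate and a median of 2 comorbidities
    among retained (non-zero) patients; ``n_blocks`` planted biclusters of
    two comorbidities each, with a planted within-pair interaction of
    ``pair_log_or`` on the readmission outcome.
    """
    k = 37
    names = [f"HCC{i + 1:02d}" for i in range(k)]
    blocks = [
        Block((2 * b, 2 * b + 1), block_fraction, p_in) for b in range(n_blocks)
    ]
    log_or = np.zeros((k, k))
    for b in range(n_blocks):
        log_or[2 * b, 2 * b + 1] = log_or[2 * b + 1, 2 * b] = pair_log_or
    return SynthConfig(
        n_cases=n_cases,
        comorbidity_names=names,
        block_spec=blocks,
        p_out=0.0436,
        planted_log_or=log_or,
        seed=seed,
    )


def planted_blocks(
    n_cases: int = 25000,
    seed: int = 0,
    n_blocks: int = 7,
    block_size: int = 4,
    p_in: float = 0.3,
    p_out: float = 0.02,
    pair_log_or: float = math.log(2.0),
) -> SynthConfig:
    """Recovery-study conditions: strong planted biclusters plus pair risk.

    ``n_blocks`` disjoint blocks of ``block_size`` comorbidities; case
    candidates split evenly over the blocks plus one block-free stratum,
    so each block holds ``n_cases / (n_blocks + 1)`` cases in expectation.
    Every within-block comorbidity pair carries a planted interaction of
    ``pair_log_or`` on the outcome.
    """
    k = n_blocks * block_size
    names = [f"HCC{i + 1:02d}" for i in range(k)]
    frac = 1.0 / (n_blocks + 1)
    blocks = [
        Block(tuple(range(b * block_size, (b + 1) * block_size)), frac, p_in)
        for b in range(n_blocks)
    ]
    log_or = np.zeros((k, k))
    for b in blocks:
        for i in b.comorbidities:
            for j in b.comorbidities:
                if i != j:
                    log_or[i, j] = pair_log_or
    return SynthConfig(
        n_cases=n_cases,
        comorbidity_names=names,
        block_spec=blocks,
        p_out=p_out,
        planted_log_or=log_or,
        seed=seed,
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    """JSON sidecar with block assignments and planted parameters."""
    payload = {
        "true_block_of_patient": truth.true_block_of_patient,
        "true_block_of_comorbidity": truth.true_block_of_comorbidity,
        "planted_log_or": truth.planted_log_or.tolist(),
        "config": {
            "n_cases": truth.config.n_cases,
            "n_controls": truth.config.n_controls,
            "comorbidity_names": truth.config.comorbidity_names,
            "block_spec": [
                [list(b.comorbidities), b.patient_fraction, b.p_in]
                for b in truth.config.block_spec
            ],
            "p_out": truth.config.p_out,
            "main_effects": truth.config.main_effects.tolist(),
            "intercept": truth.config.intercept,
            "seed": truth.config.seed,
            "max_draw_factor": truth.config.max_draw_factor,
            "generator": truth.config.generator,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> SyntheticTruth:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    c = payload["config"]
    config = SynthConfig(
        n_cases=c["n_cases"],
        n_controls=c["n_controls"],
        comorbidity_names=c["comorbidity_names"],
        block_spec=[Block(tuple(b[0]), b[1], b[2]) for b in c["block_spec"]],
        p_out=c["p_out"],
        planted_log_or=np.array(payload["planted_log_or"]),
        main_effects=np.array(c["main_effects"]),
        intercept=c["intercept"],
        seed=c["seed"],
        max_draw_factor=c["max_draw_factor"],
        generator=c["generator"],
    )
    return SyntheticTruth(
        {k: v for k, v in payload["true_block_of_patient"].items()},
        {k: v for k, v in payload["true_block_of_comorbidity"].items()},
        np.array(payload["planted_log_or"]),
        config,
    )
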
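"""Case-control cohort container and CSV round-trip.

A cohort is a binary patient x comorbidity indicator matrix plus a binary
outcome label per patient (1 = case, e.g. readmitted within 30 days;
0 = matched control).  The on-disk format is a plain CSV with header
``patient_id,outcome,<comorbidity>,...`` and 0/1 cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataValidationError

__all__ = ["CohortMatrix", "read_cohort", "write_cohort"]


@dataclass
class CohortMatrix:
    """Binary patient x comorbidity matrix with case/control outcome labels.

    Parameters
    ----------
    patient_ids : sequence of str
        Distinct patient identifiers, one per row of ``X``.
    outcome : array-like of {0, 1}
        1 for cases, 0 for controls; aligned with ``patient_ids``.
    X : array-like of {0, 1}, shape (n_patients, n_comorbidities)
        Comorbidity indicator matrix.
    comorbidity_names : sequence of str
        Distinct column labels for ``X``.
    """

    patient_ids: np.ndarray
    outcome: np.ndarray
    X: np.ndarray
    comorbidity_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.outcome = np.asarray(self.outcome, dtype=np.int8)
        self.X = np.asarray(self.X, dtype=np.int8)
        self.comorbidity_names = list(self.comorbidity_names)
        if self.X.ndim != 2:
            raise DataValidationError("X must be a 2-D matrix")
        n, k = self.X.shape
        if len(self.patient_ids) != n:
            raise DataValidationError(
                f"{len(self.patient_ids)} patient ids for {n} matrix rows"
            )
        if len(self.outcome) != n:
            raise DataValidationError(
                f"{len(self.outcome)} outcome labels for {n} matrix rows"
            )
        if len(self.comorbidity_names) != k:
            raise DataValidationError(
                f"{len(self.comorbidity_names)} column labels for {k} columns"
            )
        if len(set(self.patient_ids)) != n:
            raise DataValidationError("duplicated patient_id")
        if len(set(self.comorbidity_names)) != k:
            raise DataValidationError("duplicated comorbidity label")
        if not np.isin(self.X, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.X, (0, 1)))[0]
            raise DataValidationError(
                f"non-binary indicator value at row {bad[0]} "
                f"(patient {self.patient_ids[bad[0]]}), "
                f"column {self.comorbidity_names[bad[1]]}"
            )
        if not np.isin(self.outcome, (0, 1)).all():
            raise DataValidationError("outcome labels must be 0 or 1")

    # -- basic accessors -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_comorbidities(self) -> int:
        return self.X.shape[1]

    @property
    def is_case(self) -> np.ndarray:
        return self.outcome == 1

    @property
    def n_cases(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_controls(self) -> int:
        return int((self.outcome == 0).sum())

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.comorbidity_names.index(name)].astype(bool)

    def subset_patients(self, mask: np.ndarray) -> "CohortMatrix":
        """Row subset preserving order."""
        mask = np.asarray(mask, dtype=bool)
        return CohortMatrix(
            self.patient_ids[mask], self.outcome[mask], self.X[mask],
            list(self.comorbidity_names),
        )

    def subset_comorbidities(self, names: list[str]) -> "CohortMatrix":
        idx = [self.comorbidity_names.index(n) for n in names]
        return CohortMatrix(
            self.patient_ids.copy(), self.outcome.copy(), self.X[:, idx],
            list(names),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.comorbidity_names)
        df.insert(0, "outcome", self.outcome)
        df.insert(0, "patient_id", self.patient_ids)
        return df

    def equals(self, other: "CohortMatrix") -> bool:
        return (
            list(self.patient_ids) == list(other.patient_ids)
            and self.comorbidity_names == other.comorbidity_names
            and np.array_equal(self.outcome, other.outcome)
            and np.array_equal(self.X, other.X)
        )


def write_cohort(cohort: CohortMatrix, path) -> None:
    """Write a cohort as UTF-8 CSV (``patient_id,outcome,<comorbidity>...``)."""
    cohort.to_dataframe().to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> CohortMatrix:
    """Read a cohort CSV written by :func:`write_cohort`, validating cells.

    Raises
    ------
    DataValidationError
        Empty file / missing header, non-binary indicator cells (named by
        row and column), or duplicated patient ids.
    """
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except pd.errors.EmptyDataError:
        raise DataValidationError(f"{path}: no header") from None
    if list(df.columns[:2]) != ["patient_id", "outcome"]:
        raise DataValidationError(
            f"{path}: header must start with patient_id,outcome "
            f"(got {list(df.columns[:2])})"
        )
    names = list(df.columns[2:])
    X = df[names].to_numpy()
    if X.size and not np.isin(X, (0, 1)).all():
        bad = np.argwhere(~np.isin(X, (0, 1)))[0]
        raise DataValidationError(
            f"{path}: non-binary value {X[bad[0], bad[1]]!r} at data row "
            f"{bad[0]}, column {names[bad[1]]}"
        )
    return CohortMatrix(
        df["patient_id"].to_numpy(dtype=object),
        df["outcome"].to_numpy(),
        X,
        names,
    )
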
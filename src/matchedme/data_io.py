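"""Reading, validation and pre-processing of matched case-control study tables.

The central container is :class:`MatchedStudy`: subjects grouped into matched
sets, each set holding exactly one case (stored first) and one or more
controls.  Exposures are surrogate measurements on the log scale; confounders
are taken to be precisely measured.  Concentration tables on the original
(e.g. ppb) scale are handled by :class:`RawConcentrationTable`, with the
standard pre-processing steps: substitution of non-detects by half the limit
of detection, and transformation to log-molar units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


class StudyValidationError(ValueError):
    """Raised when a study table violates the matched-design invariants."""


@dataclass(frozen=True)
class Subject:
    """One study subject: matched-set label, case status, exposures, confounders."""

    set_id: object
    is_case: int
    w: np.ndarray  # length-P surrogate exposures, log scale
    z: np.ndarray  # length-K confounders (K may be 0)


@dataclass
class MatchedStudy:
    """An individually matched case-control study (1 case : >=1 controls per set).

    Subjects are stored in flat arrays ordered set by set, with the case first
    within each set.  ``W`` holds the observed (surrogate) exposures on the log
    scale, ``Z`` the precisely measured confounders.
    """

    set_ids: list
    sizes: np.ndarray          # (N,) members per set, each >= 2
    W: np.ndarray              # (S, P)
    Z: np.ndarray              # (S, K)
    exposure_names: list = field(default_factory=list)
    confounder_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim == 1:
            self.Z = self.Z.reshape(len(self.Z), 0) if self.Z.size == 0 else self.Z.reshape(-1, 1)
        if self.Z.size == 0:
            self.Z = np.zeros((self.W.shape[0], 0))
        if len(self.sizes) < 2:
            raise StudyValidationError("a study needs at least 2 matched sets")
        if np.any(self.sizes < 2):
            bad = [self.set_ids[i] for i in np.where(self.sizes < 2)[0]]
            raise StudyValidationError(f"matched sets with fewer than 2 members: {bad}")
        if self.sizes.sum() != self.W.shape[0]:
            raise StudyValidationError("sum of set sizes does not match number of subjects")
        if self.Z.shape[0] != self.W.shape[0]:
            raise StudyValidationError("W and Z disagree on the number of subjects")
        if not np.all(np.isfinite(self.W)):
            raise StudyValidationError("non-finite exposure values")
        if not np.all(np.isfinite(self.Z)):
            raise StudyValidationError("non-finite confounder values")
        if not self.exposure_names:
            self.exposure_names = [f"x{p + 1}" for p in range(self.P)]
        if not self.confounder_names:
            self.confounder_names = [f"z{k + 1}" for k in range(self.K)]

    # -- basic dimensions -------------------------------------------------
    @property
    def n_sets(self) -> int:
        return len(self.sizes)

    @property
    def n_subjects(self) -> int:
        return int(self.sizes.sum())

    @property
    def P(self) -> int:
        return self.W.shape[1]

    @property
    def K(self) -> int:
        return self.Z.shape[1]

    @property
    def offsets(self) -> np.ndarray:
        """Row index of the first member (the case) of each set."""
        return np.concatenate(([0], np.cumsum(self.sizes)[:-1]))

    @property
    def set_index(self) -> np.ndarray:
        """(S,) index of the matched set each subject belongs to."""
        return np.repeat(np.arange(self.n_sets), self.sizes)

    @property
    def is_case(self) -> np.ndarray:
        y = np.zeros(self.n_subjects, dtype=int)
        y[self.offsets] = 1
        return y

    def subjects(self) -> Iterator[Subject]:
        y = self.is_case
        sidx = self.set_index
        for r in range(self.n_subjects):
            yield Subject(self.set_ids[sidx[r]], int(y[r]), self.W[r], self.Z[r])

    def set_slices(self) -> Iterator[slice]:
        for off, n in zip(self.offsets, self.sizes):
            yield slice(off, off + n)


@dataclass
class RawConcentrationTable:
    """Per-subject concentrations on the original scale (e.g. ppb).

    ``nondetect`` flags values below the assay's limit of detection; ``lod``
    and the molar-to-concentration conversion factors ``m`` are per exposure.
    """

    values: np.ndarray       # (S, P) concentrations, original scale
    nondetect: np.ndarray    # (S, P) bool
    lod: np.ndarray          # (P,)
    m: np.ndarray            # (P,) concentration units per molar unit
    exposure_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.nondetect = np.atleast_2d(np.asarray(self.nondetect, dtype=bool))
        self.lod = np.asarray(self.lod, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.values.shape != self.nondetect.shape:
            raise ValueError("values and nondetect must have the same shape")
        if np.any(self.lod <= 0):
            raise ValueError("limits of detection must be positive")
        if np.any(self.m <= 0):
            raise ValueError("unit conversion factors must be positive")
        if not self.exposure_names:
            self.exposure_names = [f"x{p + 1}" for p in range(self.values.shape[1])]


def read_study(
    path,
    exposure_cols: Sequence[str],
    confounder_cols: Sequence[str] = (),
    set_col: str = "set",
    case_col: str = "case",
) -> MatchedStudy:
    """Read a study CSV and group subjects into matched sets, case first.

    The file must contain one row per subject.  Within each set the case is
    placed first; controls keep their file order.  Sets appear in order of
    first appearance in the file.

    Raises
    ------
    StudyValidationError
        If any used column has a missing value (reported with its row index)
        or any set does not contain exactly one case (reported by set label).
    """
    df = pd.read_csv(path)
    used = [set_col, case_col, *exposure_cols, *confounder_cols]
    missing_cols = [c for c in used if c not in df.columns]
    if missing_cols:
        raise StudyValidationError(f"missing columns in {path}: {missing_cols}")
    na = df[used].isna()
    if na.to_numpy().any():
        row = int(np.where(na.any(axis=1))[0][0])
        raise StudyValidationError(f"missing value in row {row} of {path}")

    set_ids, sizes, rows = [], [], []
    for sid, grp in df.groupby(set_col, sort=False):
        cases = grp.index[grp[case_col].astype(int) == 1]
        if len(cases) != 1:
            raise StudyValidationError(
                f"set {sid!r} has {len(cases)} cases; exactly one is required"
            )
        order = [cases[0], *[i for i in grp.index if i != cases[0]]]
        if len(order) < 2:
            raise StudyValidationError(f"set {sid!r} has no controls")
        set_ids.append(sid)
        sizes.append(len(order))
        rows.extend(order)

    sub = df.loc[rows]
    return MatchedStudy(
        set_ids=set_ids,
        sizes=np.array(sizes),
        W=sub[list(exposure_cols)].to_numpy(dtype=float),
        Z=sub[list(confounder_cols)].to_numpy(dtype=float)
        if confounder_cols
        else np.zeros((len(sub), 0)),
        exposure_names=list(exposure_cols),
        confounder_names=list(confounder_cols),
    )


def apply_lod(table: RawConcentrationTable) -> tuple[RawConcentrationTable, np.ndarray]:
    """Replace every non-detect by half its limit of detection.

    Returns the processed table (non-detect flags cleared, so the operation is
    idempotent) and the per-exposure count of substitutions.
    """
    detected = table.values[~table.nondetect]
    if np.any(detected < 0):
        raise ValueError("negative detected concentration")
    values = table.values.copy()
    values[table.nondetect] = np.broadcast_to(table.lod / 2.0, values.shape)[table.nondetect]
    counts = table.nondetect.sum(axis=0)
    out = replace(
        table, values=values, nondetect=np.zeros_like(table.nondetect, dtype=bool)
    )
    return out, counts


def to_log_molar(table: RawConcentrationTable) -> np.ndarray:
    """Transform concentrations to log-molar units: log(c / m_p), natural log."""
    if np.any(table.values <= 0):
        raise ValueError(
            "non-positive concentrations present; run apply_lod before to_log_molar"
        )
    return np.log(table.values / table.m)


def write_summary(summaries, path, provenance: dict | None = None) -> None:
    """Write odds-ratio summaries to CSV, with a JSON mirror of full provenance.

    One row per parameter: name, posterior mean OR, 2.5% and 97.5% posterior
    quantiles of the OR, posterior mean and SD of the coefficient, R-hat and
    MCSE.  The JSON mirror (same stem, ``.json``) additionally embeds the
    ``provenance`` dict (seeds, priors, error variances) when given.
    """
    frames = [s.to_frame() for s in summaries] if isinstance(summaries, (list, tuple)) else [summaries.to_frame()]
    if not frames:
        raise ValueError("no summaries to write")
    df = pd.concat(frames, ignore_index=True)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    payload = {"summary": df.to_dict(orient="records")}
    if provenance is not None:
        payload["provenance"] = provenance
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2, default=str))
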
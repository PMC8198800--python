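"""Ligand-metal stability-constant records: I/O, curation, splitting, scaling.

The regression endpoint throughout the package is logK, the base-10
logarithm of the stability (formation) constant of a lanthanide(III)
complex.  Records carry the measurement conditions (ionic strength in
mol/L, temperature in degrees Celsius, method label) used by the
curation filters, and a ligand:metal stoichiometry label ("1:1" or
"2:1") so one pipeline can serve both complex types.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .exceptions import (
    EmptyInputError,
    InputFormatError,
    InvalidSmilesError,
    ParameterError,
)

RDLogger.DisableLog("rdApp.*")

#: Lanthanides modelled; Pm has no stable isotope and no measured constants.
LANTHANIDES = (
    "La", "Ce", "Pr", "Nd", "Sm", "Eu", "Gd",
    "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu",
)

#: Ligand:metal ratios supported (one or two ligands per metal ion).
STOICHIOMETRIES = ("1:1", "2:1")

_CSV_COLUMNS = (
    "smiles", "metal", "stoich", "logk",
    "ionic_strength", "temperature", "method", "source",
)


@dataclass(frozen=True)
class LigandRecord:
    """One literature (or synthetic) stability-constant measurement."""

    smiles: str
    metal: str
    logk: float
    stoichiometry: str = "1:1"
    ionic_strength: float | None = None  # mol/L
    temperature: float | None = None     # degrees C
    method: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.metal not in LANTHANIDES:
            raise ValueError(f"unknown lanthanide label {self.metal!r}")
        if self.stoichiometry not in STOICHIOMETRIES:
            raise ValueError(f"stoichiometry must be one of {STOICHIOMETRIES}")
        if not math.isfinite(self.logk):
            raise ValueError("logk must be finite")


@dataclass(frozen=True)
class CurationCriteria:
    """Condition windows applied when selecting literature constants.

    Defaults keep measurements at ionic strength 0.1-0.3 mol/L and
    20-25 degrees C; records with missing conditions are kept unless
    ``require_conditions`` is set.
    """

    ionic_strength_range: tuple[float, float] = (0.1, 0.3)
    temperature_range: tuple[float, float] = (20.0, 25.0)
    require_conditions: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (self.ionic_strength_range, self.temperature_range):
            if lo > hi:
                raise ValueError("interval lower bound exceeds upper bound")


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split and cross-validation fold layout."""

    test_fraction: float = 0.2
    n_folds: int = 10
    n_strata_bins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_strata_bins < 2:
            raise ValueError("n_strata_bins must be >= 2")


@dataclass(frozen=True)
class ScalerState:
    """Fitted MinMax scaling parameters for features and target.

    Binary fingerprint columns are left numerically unchanged (their
    min is 0 and max is 1); constant columns map to 0.
    """

    feature_min: np.ndarray
    feature_max: np.ndarray
    target_min: float
    target_max: float

    def transform_features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.feature_max - self.feature_min
        out = np.zeros_like(X)
        ok = span > 0
        out[:, ok] = (X[:, ok] - self.feature_min[ok]) / span[ok]
        return out

    def inverse_features(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.asarray(Xs, dtype=float)
        span = self.feature_max - self.feature_min
        out = np.empty_like(Xs)
        ok = span > 0
        out[:, ok] = Xs[:, ok] * span[ok] + self.feature_min[ok]
        out[:, ~ok] = self.feature_min[~ok]
        return out

    def transform_target(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        span = self.target_max - self.target_min
        if span <= 0:
            return np.zeros_like(y)
        return (y - self.target_min) / span

    def inverse_target(self, ys: np.ndarray) -> np.ndarray:
        ys = np.asarray(ys, dtype=float)
        span = self.target_max - self.target_min
        if span <= 0:
            return np.full_like(ys, self.target_min)
        return ys * span + self.target_min


def fit_scaler(X: np.ndarray, y: np.ndarray) -> ScalerState:
    """Fit MinMax scaling on a feature matrix and target vector."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-D matrix")
    return ScalerState(
        feature_min=X.min(axis=0),
        feature_max=X.max(axis=0),
        target_min=float(y.min()),
        target_max=float(y.max()),
    )


# ---------------------------------------------------------------------------
# SMILES standardization

_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()


def standardize_smiles(smiles: str) -> str:
    """Sanitize, keep the largest organic fragment, canonicalize.

    Raises :class:`InvalidSmilesError` when the string does not parse.
    No explicit hydrogens are added; the canonical SMILES acts as the
    structure key for duplicate detection.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"cannot parse SMILES {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise InvalidSmilesError(f"empty molecule from SMILES {smiles!r}")
    mol = _FRAGMENT_CHOOSER.choose(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# CSV input / output


def _parse_optional_float(text: str) -> float | None:
    text = text.strip()
    return float(text) if text else None


def read_records(path: str | Path) -> tuple[list[LigandRecord], list[dict]]:
    """Read ligand records from CSV.

    Returns ``(records, rejections)`` where each rejection is a dict
    with the 1-based data ``row`` and a human-readable ``reason``; bad
    rows are reported rather than silently dropped.  SMILES are
    standardized on read.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path} is empty")
        missing = {"smiles", "metal", "logk"} - set(reader.fieldnames)
        if missing:
            raise InputFormatError(
                f"{path} lacks mandatory column(s): {', '.join(sorted(missing))}"
            )
        records: list[LigandRecord] = []
        rejections: list[dict] = []
        for row_no, row in enumerate(reader, start=1):
            try:
                records.append(
                    LigandRecord(
                        smiles=standardize_smiles(row["smiles"]),
                        metal=row["metal"].strip(),
                        stoichiometry=(row.get("stoich") or "1:1").strip(),
                        logk=float(row["logk"]),
                        ionic_strength=_parse_optional_float(row.get("ionic_strength") or ""),
                        temperature=_parse_optional_float(row.get("temperature") or ""),
                        method=(row.get("method") or "").strip() or None,
                        source=(row.get("source") or "").strip() or None,
                    )
                )
            except (InvalidSmilesError, ValueError) as exc:
                rejections.append({"row": row_no, "reason": str(exc)})
    if not records and not rejections:
        raise EmptyInputError(f"{path} contains a header but no data rows")
    return records, rejections


def write_records(records: Iterable[LigandRecord], path: str | Path) -> None:
    """Write records as UTF-8 comma-separated CSV (empty fields = missing)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow([
                r.smiles, r.metal, r.stoichiometry, repr(r.logk),
                "" if r.ionic_strength is None else repr(r.ionic_strength),
                "" if r.temperature is None else repr(r.temperature),
                r.method or "", r.source or "",
            ])


def write_rejections(rejections: Sequence[dict], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=["row", "reason"])
        writer.writeheader()
        writer.writerows(rejections)


# ---------------------------------------------------------------------------
# Curation


def _in_window(value: float | None, window: tuple[float, float]) -> bool | None:
    if value is None:
        return None
    return window[0] <= value <= window[1]


def _condition_distance(record: LigandRecord) -> float:
    """Distance of the measurement conditions from 25 C / 0.1 M.

    Scaled by the half-width of each curation window so the two units
    are commensurate; missing conditions sort last.
    """
    if record.temperature is None or record.ionic_strength is None:
        return math.inf
    return abs(record.temperature - 25.0) / 2.5 + abs(record.ionic_strength - 0.1) / 0.1


def _resolve_duplicates(group: list[LigandRecord]) -> LigandRecord:
    # Preference cascade: potentiometric method, then conditions closest
    # to 25 C and 0.1 M, then the median-logk member of the group.
    pot = [r for r in group if r.method and "potentiometric" in r.method.lower()]
    cand = pot if pot else list(group)
    if len(cand) > 1:
        dists = [_condition_distance(r) for r in cand]
        best = min(dists)
        if math.isfinite(best):
            cand = [r for r, d in zip(cand, dists) if d == best]
    if len(cand) > 1:
        cand = sorted(cand, key=lambda r: r.logk)
        cand = [cand[(len(cand) - 1) // 2]]
    return cand[0]


def curate(
    records: Sequence[LigandRecord],
    criteria: CurationCriteria | None = None,
) -> tuple[list[LigandRecord], list[dict]]:
    """Apply the condition filters and collapse duplicate measurements.

    Returns ``(kept, rejections)``.  Duplicates share the key
    (standardized SMILES, metal, stoichiometry); each group is reduced
    to a single record by the method-preference cascade.  The operation
    is idempotent.
    """
    criteria = criteria or CurationCriteria()
    kept: list[LigandRecord] = []
    rejections: list[dict] = []
    for i, r in enumerate(records):
        checks = {
            "ionic_strength": _in_window(r.ionic_strength, criteria.ionic_strength_range),
            "temperature": _in_window(r.temperature, criteria.temperature_range),
        }
        bad = [name for name, ok in checks.items() if ok is False]
        missing = [name for name, ok in checks.items() if ok is None]
        if bad:
            rejections.append({"row": i, "reason": f"{bad[0]} outside curation window"})
            continue
        if missing and criteria.require_conditions:
            rejections.append({"row": i, "reason": f"missing {missing[0]}"})
            continue
        kept.append(r)

    groups: dict[tuple[str, str, str], list[LigandRecord]] = {}
    order: list[tuple[str, str, str]] = []
    for r in kept:
        key = (standardize_smiles(r.smiles), r.metal, r.stoichiometry)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    resolved = []
    for key in order:
        group = groups[key]
        winner = _resolve_duplicates(group)
        if len(group) > 1:
            for r in group:
                if r is not winner:
                    rejections.append({
                        "row": records.index(r) if r in records else -1,
                        "reason": "duplicate measurement superseded",
                    })
        resolved.append(winner)
    return resolved, rejections


# ---------------------------------------------------------------------------
# Splitting


def _quantile_bins(y: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each sample to an equal-frequency bin; tiny bins merged."""
    order = np.argsort(y, kind="stable")
    labels = np.empty(len(y), dtype=int)
    # equal-count slicing of the sorted order handles ties deterministically
    slices = np.array_split(order, n_bins)
    b = 0
    for sl in slices:
        if len(sl) == 0:
            continue
        labels[sl] = b
        b += 1
    # merge bins with fewer than 2 members into their left neighbour
    for lab in range(b):
        if (labels == lab).sum() < 2 and b > 1:
            target = lab - 1 if lab > 0 else lab + 1
            labels[labels == lab] = target
    # re-densify labels
    uniq = np.unique(labels)
    remap = {u: i for i, u in enumerate(uniq)}
    return np.array([remap[v] for v in labels])


def stratified_split(
    y: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint-stratified train/test split.

    The endpoint is cut into ``n_strata_bins`` equal-frequency bins and
    the test fraction is drawn within each bin (largest-remainder
    allocation keeps the global test size at ``round(f*n)`` and the
    per-bin deviation under one record).  Deterministic per seed.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < spec.n_strata_bins:
        raise ParameterError(
            f"{n} records cannot populate {spec.n_strata_bins} strata"
        )
    n_test = int(round(spec.test_fraction * n))
    if n_test < 1:
        raise ParameterError("test_fraction * n_records < 1")
    labels = _quantile_bins(y, spec.n_strata_bins)
    rng = np.random.default_rng(spec.seed)

    bins = np.unique(labels)
    sizes = np.array([(labels == b).sum() for b in bins])
    exact = spec.test_fraction * sizes
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    shortfall = n_test - counts.sum()
    if shortfall > 0:
        # deterministic largest-remainder top-up (ties broken by bin index)
        for b in np.argsort(-remainder, kind="stable")[:shortfall]:
            counts[b] += 1
    counts = np.minimum(counts, sizes)

    test_idx: list[np.ndarray] = []
    for b, c in zip(bins, counts):
        members = np.flatnonzero(labels == b)
        test_idx.append(rng.choice(members, size=c, replace=False))
    test = np.sort(np.concatenate(test_idx)).astype(int)
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def make_folds(
    train_idx: np.ndarray, spec: SplitSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffle the training set and partition it into CV folds.

    Each pair is (fit indices, validation indices); the validation sets
    are disjoint and their union is the training set, so with the
    default 10 folds every sub-model trains on 90% and validates on 10%.
    """
    train_idx = np.asarray(train_idx)
    if len(train_idx) < spec.n_folds:
        raise ParameterError(
            f"{len(train_idx)} training records < {spec.n_folds} folds"
        )
    rng = np.random.default_rng(spec.seed + 1)
    shuffled = rng.permutation(train_idx)
    folds = []
    for val in np.array_split(shuffled, spec.n_folds):
        fit = np.setdiff1d(train_idx, val)
        folds.append((fit, np.sort(val)))
    return folds
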
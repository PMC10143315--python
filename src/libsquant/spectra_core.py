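"""Core domain types for LIBS spectra, CSV I/O, and the replicate-aware split.

A :class:`SpectraSet` is the currency of the whole pipeline: an
``n_samples x n_channels`` intensity matrix on a shared wavelength axis,
with per-sample metadata (brand, concentration-gradient group, replicate,
and reference concentrations of Cd, Cu and Pb in mg/kg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ELEMENTS = ("Cd", "Cu", "Pb")

#: metadata columns, in CSV order, preceding the wavelength columns
META_COLUMNS = ("sample_id", "brand", "group", "replicate", "Cd", "Cu", "Pb")


class SpectraFormatError(ValueError):
    """Raised when a spectra CSV or a SpectraSet violates the format contract."""


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly ascending wavelength axis in nm."""

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size == 0:
            raise SpectraFormatError("wavelength axis must be a nonempty 1-D array")
        if not np.all(np.diff(wl) > 0):
            raise SpectraFormatError("wavelengths must be strictly ascending")

    @property
    def n_channels(self) -> int:
        return int(self.wavelengths.size)

    @classmethod
    def default(cls, n_channels: int = 1024, low: float = 210.0, high: float = 231.0) -> "SpectralAxis":
        """The instrument axis: 1024 channels spanning 210–231 nm."""
        return cls(np.linspace(low, high, n_channels))

    def index_of(self, wavelength: float) -> int:
        """Index of the channel closest to ``wavelength`` (nm)."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength)))


@dataclass(frozen=True)
class SampleMeta:
    """Identity and reference chemistry of one pellet spectrum."""

    sample_id: str
    brand: int
    group: int
    replicate: int
    conc: dict  # element -> mg/kg

    def __post_init__(self):
        for name, val, hi in (("brand", self.brand, 8), ("group", self.group, 8), ("replicate", self.replicate, 3)):
            if not isinstance(val, (int, np.integer)) or val < 1:
                raise SpectraFormatError(f"{name} must be a positive integer, got {val!r}")
        for el in ELEMENTS:
            if el not in self.conc:
                raise SpectraFormatError(f"missing concentration for {el} in sample {self.sample_id}")
            if self.conc[el] < 0:
                raise SpectraFormatError(f"negative {el} concentration in sample {self.sample_id}")


@dataclass
class SpectraSet:
    """Sample-by-wavelength intensity matrix plus aligned metadata."""

    axis: SpectralAxis
    intensities: np.ndarray
    metas: list = field(default_factory=list)

    def __post_init__(self):
        X = np.asarray(self.intensities, dtype=float)
        if X.ndim != 2:
            X = X.reshape(-1, self.axis.n_channels)
        self.intensities = X
        if X.shape[0] != len(self.metas):
            raise SpectraFormatError(
                f"{X.shape[0]} intensity rows but {len(self.metas)} metadata entries"
            )
        if X.shape[1] != self.axis.n_channels:
            raise SpectraFormatError(
                f"{X.shape[1]} columns but axis has {self.axis.n_channels} channels"
            )
        if X.size and not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))[0]
            raise SpectraFormatError(f"non-finite intensity at row {bad[0]}, channel {bad[1]}")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def concentrations(self, element: str) -> np.ndarray:
        """Reference concentrations (mg/kg) for one element, sample order."""
        if element not in ELEMENTS:
            raise KeyError(f"unknown element {element!r}")
        return np.array([m.conc[element] for m in self.metas], dtype=float)

    def subset(self, idx) -> "SpectraSet":
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(self.axis, self.intensities[idx], [self.metas[i] for i in idx])

    def sample_ids(self) -> list:
        return [m.sample_id for m in self.metas]


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/test row indices from a replicate-aware split."""

    train_idx: tuple
    test_idx: tuple
    seed: int

    def __post_init__(self):
        if set(self.train_idx) & set(self.test_idx):
            raise SpectraFormatError("train and test indices overlap")

    def to_json(self, spectra: SpectraSet | None = None) -> str:
        payload = {"train_idx": list(self.train_idx), "test_idx": list(self.test_idx), "seed": self.seed}
        if spectra is not None:
            ids = spectra.sample_ids()
            payload["train_ids"] = [ids[i] for i in self.train_idx]
            payload["test_ids"] = [ids[i] for i in self.test_idx]
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        d = json.loads(text)
        return cls(tuple(d["train_idx"]), tuple(d["test_idx"]), int(d["seed"]))


def _wavelength_header(axis: SpectralAxis) -> list:
    return [f"{w:.4f}" for w in axis.wavelengths]


def save_spectra(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet as CSV: 7 metadata columns then one column per wavelength.

    Wavelength headers carry 4 decimals; intensities are written at full float
    precision (round-trip exact through :func:`load_spectra`).
    """
    meta_rows = {
        "sample_id": [m.sample_id for m in spectra.metas],
        "brand": [m.brand for m in spectra.metas],
        "group": [m.group for m in spectra.metas],
        "replicate": [m.replicate for m in spectra.metas],
    }
    for el in ELEMENTS:
        meta_rows[el] = [m.conc[el] for m in spectra.metas]
    df = pd.DataFrame(meta_rows)
    spec_df = pd.DataFrame(spectra.intensities, columns=_wavelength_header(spectra.axis))
    out = pd.concat([df, spec_df.set_index(df.index)], axis=1)
    if spectra.n_samples == 0:
        # header-only file: pandas concat drops columns of empty frames
        header = ",".join(list(META_COLUMNS) + _wavelength_header(spectra.axis))
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header + "\n")
        return
    out.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def load_spectra(path) -> SpectraSet:
    """Read a spectra CSV written in the :func:`save_spectra` dialect.

    Raises :class:`SpectraFormatError` naming the offending row/column for
    malformed headers, duplicated wavelengths, non-numeric cells or ragged rows.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw_header = fh.readline().strip().split(",")
    raw_wl = raw_header[len(META_COLUMNS):]
    if len(set(raw_wl)) != len(raw_wl):
        raise SpectraFormatError(f"{path}: wavelength headers must be unique and ascending")
    try:
        df = pd.read_csv(path, dtype={"sample_id": str})
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraFormatError(f"malformed CSV {path}: {exc}") from exc
    cols = list(df.columns)
    if cols[: len(META_COLUMNS)] != list(META_COLUMNS):
        raise SpectraFormatError(
            f"{path}: expected metadata columns {META_COLUMNS}, got {cols[:7]}"
        )
    wl_cols = cols[len(META_COLUMNS):]
    if not wl_cols:
        raise SpectraFormatError(f"{path}: no wavelength columns")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavelength header: {exc}") from exc
    if len(set(wl_cols)) != len(wl_cols) or not np.all(np.diff(wavelengths) > 0):
        raise SpectraFormatError(f"{path}: wavelength headers must be unique and ascending")
    axis = SpectralAxis(wavelengths)

    metas = []
    for i, row in df.iterrows():
        try:
            metas.append(
                SampleMeta(
                    sample_id=str(row["sample_id"]),
                    brand=int(row["brand"]),
                    group=int(row["group"]),
                    replicate=int(row["replicate"]),
                    conc={el: float(row[el]) for el in ELEMENTS},
                )
            )
        except (TypeError, ValueError) as exc:
            raise SpectraFormatError(f"{path}: bad metadata in row {i}: {exc}") from exc
    X = df[wl_cols].to_numpy(dtype=float) if len(df) else np.empty((0, axis.n_channels))
    if X.size and not np.all(np.isfinite(X)):
        r, c = np.argwhere(~np.isfinite(X))[0]
        raise SpectraFormatError(f"{path}: non-numeric intensity at row {r}, column {wl_cols[c]}")
    return SpectraSet(axis, X, metas)


def split_by_replicate(spectra: SpectraSet, n_train_reps: int = 2, seed: int = 0) -> SplitSpec:
    """Partition rows so each (brand, group) contributes ``n_train_reps``
    randomly chosen replicates to the training set and the rest to the test set.

    With the study design (8 brands x 8 groups x 3 replicates, n_train_reps=2)
    this yields 128 training and 64 test spectra. Randomness comes from a
    dedicated generator seeded per call; the same seed reproduces the split.
    """
    groups: dict = {}
    for i, m in enumerate(spectra.metas):
        groups.setdefault((m.brand, m.group), []).append(i)
    counts = {key: len(v) for key, v in groups.items()}
    if counts:
        n_reps = next(iter(counts.values()))
        bad = sorted(k for k, v in counts.items() if v != n_reps)
        if bad:
            raise SpectraFormatError(f"unequal replicate counts for (brand, group) pairs: {bad}")
        if n_train_reps >= n_reps:
            raise ValueError(f"n_train_reps={n_train_reps} must be < replicate count {n_reps}")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for key in sorted(groups):
        idx = sorted(groups[key], key=lambda i: spectra.metas[i].replicate)
        chosen = rng.choice(len(idx), size=n_train_reps, replace=False)
        chosen_set = set(int(c) for c in chosen)
        for j, i in enumerate(idx):
            (train if j in chosen_set else test).append(i)
    return SplitSpec(tuple(sorted(train)), tuple(sorted(test)), seed)
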
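"""Landmark dataset containers and TPS/CSV input-output.

A landmark dataset is a stack of 2-D landmark configurations, one per
specimen, with taxonomic and provenance metadata (species, genus, sampling
site, date, observer, replicate).  Coordinates follow the mathematical
convention: x increases rightward, y increases upward.  Data digitized in
image pixel coordinates (y down) must be flipped by the producer before
import; superimposition disallows reflections, so the convention matters.

Landmark indices are 1-based in files and error messages, 0-based in code.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Metadata columns carried with every dataset, in canonical order.
META_COLUMNS = ("specimen_id", "species", "genus", "site", "date",
                "observer", "replicate")


class LandmarkFormatError(ValueError):
    """Raised on malformed or inconsistent landmark files."""


class LandmarkDataset:
    """Specimens x k landmarks x 2 raw coordinates plus metadata.

    Parameters
    ----------
    coords : array-like, shape (n_specimens, k, 2)
        Raw planar landmark coordinates in arbitrary but common units.
        All configurations must share the same fixed landmark order.
    meta : pandas.DataFrame, optional
        One row per specimen.  Missing columns from ``META_COLUMNS`` are
        added with empty strings; missing ``specimen_id`` values are
        autogenerated.
    """

    def __init__(self, coords, meta: pd.DataFrame | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 2:
            raise ValueError(
                f"coords must have shape (n, k, 2), got {coords.shape}")
        if coords.shape[1] < 3:
            raise ValueError(f"need k >= 3 landmarks, got k={coords.shape[1]}")
        if not np.all(np.isfinite(coords)):
            bad = np.argwhere(~np.isfinite(coords).all(axis=(1, 2)))[0, 0]
            raise ValueError(f"non-finite coordinates in specimen {bad}")
        n = coords.shape[0]
        if meta is None:
            meta = pd.DataFrame(index=range(n))
        elif len(meta) != n:
            raise ValueError(f"meta has {len(meta)} rows for {n} specimens")
        meta = meta.reset_index(drop=True).copy()
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = ""
        meta = meta[list(META_COLUMNS)].astype(str)
        blank = meta["specimen_id"] == ""
        if blank.any():
            meta.loc[blank, "specimen_id"] = [
                f"s{i + 1}" for i in np.flatnonzero(blank.to_numpy())]
        keys = meta[["specimen_id", "observer", "replicate"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(
                f"duplicate (specimen, observer, replicate) key: {dup}")
        self.coords = coords
        self.meta = meta

    # -- basic accessors -------------------------------------------------
    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        """Number of landmarks per configuration."""
        return self.coords.shape[1]

    @property
    def specimen_ids(self) -> np.ndarray:
        return self.meta["specimen_id"].to_numpy()

    @property
    def species(self) -> np.ndarray:
        return self.meta["species"].to_numpy()

    @property
    def genus(self) -> np.ndarray:
        return self.meta["genus"].to_numpy()

    def __len__(self) -> int:
        return self.n_specimens

    def subset(self, index) -> "LandmarkDataset":
        """Return a new dataset for a boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return LandmarkDataset(self.coords[index],
                               self.meta.iloc[index].reset_index(drop=True))

    def copy(self) -> "LandmarkDataset":
        return LandmarkDataset(self.coords.copy(), self.meta.copy())

    @staticmethod
    def concat(datasets) -> "LandmarkDataset":
        """Stack datasets with identical k into one dataset."""
        ks = {d.k for d in datasets}
        if len(ks) != 1:
            raise ValueError(f"landmark counts differ across datasets: {ks}")
        coords = np.concatenate([d.coords for d in datasets], axis=0)
        meta = pd.concat([d.meta for d in datasets], ignore_index=True)
        return LandmarkDataset(coords, meta)


# ---------------------------------------------------------------------------
# TPS dialect
# ---------------------------------------------------------------------------

def _parse_tps(text: str):
    records, coords, ids = [], None, {}
    k_expected = None
    lines = text.splitlines()
    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise LandmarkFormatError(
                f"line {i + 1}: expected 'LM=' record header, got {line!r}")
        record_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise LandmarkFormatError(
                f"line {i + 1}: malformed landmark count {line!r}") from None
        if k_expected is None:
            k_expected = k
        elif k != k_expected:
            raise LandmarkFormatError(
                f"record {record_no}: LM={k} differs from LM={k_expected} "
                f"of record 1")
        i += 1
        pts = []
        for j in range(k):
            if i >= len(lines):
                raise LandmarkFormatError(
                    f"record {record_no}: file ends inside coordinate block")
            parts = lines[i].split()
            if len(parts) != 2:
                raise LandmarkFormatError(
                    f"line {i + 1}: expected 'x y', got {lines[i]!r}")
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise LandmarkFormatError(
                    f"line {i + 1}: non-numeric coordinate "
                    f"{lines[i]!r}") from None
            i += 1
        meta = {"specimen_id": ""}
        while i < len(lines) and lines[i].strip() and \
                not lines[i].strip().upper().startswith("LM="):
            tagline = lines[i].strip()
            if "=" in tagline:
                tag, value = tagline.split("=", 1)
                tag = tag.strip().upper()
                if tag == "ID":
                    meta["specimen_id"] = value.strip()
                elif tag == "IMAGE":
                    meta["image"] = value.strip()
            i += 1
        records.append((np.asarray(pts), meta))
    if not records:
        raise LandmarkFormatError("no TPS records found")
    coords = np.stack([r[0] for r in records])
    meta = pd.DataFrame([r[1] for r in records]).drop(
        columns=["image"], errors="ignore")
    return LandmarkDataset(coords, meta)


def _write_tps(dataset: LandmarkDataset) -> str:
    out = []
    for i in range(dataset.n_specimens):
        out.append(f"LM={dataset.k}")
        for x, y in dataset.coords[i]:
            out.append(f"{x:.12g} {y:.12g}")
        out.append(f"ID={dataset.meta.at[i, 'specimen_id']}")
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# CSV dialect (canonical)
# ---------------------------------------------------------------------------

def _coordinate_columns(k: int):
    cols = []
    for j in range(1, k + 1):
        cols += [f"x{j}", f"y{j}"]
    return cols


def _parse_csv(path) -> LandmarkDataset:
    frame = pd.read_csv(path, dtype={c: str for c in META_COLUMNS},
                        keep_default_na=False,
                        float_precision="round_trip")
    coord_cols = [c for c in frame.columns if c not in META_COLUMNS]
    k = len(coord_cols) // 2
    expected = _coordinate_columns(k)
    if coord_cols != expected:
        raise LandmarkFormatError(
            f"coordinate columns must be x1,y1,...,x{k},y{k}; "
            f"got {coord_cols[:6]}...")
    try:
        flat = frame[coord_cols].to_numpy(dtype=float)
    except ValueError as exc:
        raise LandmarkFormatError(f"non-numeric coordinate: {exc}") from None
    meta = frame[[c for c in META_COLUMNS if c in frame.columns]]
    return LandmarkDataset(flat.reshape(len(frame), k, 2), meta)


def _write_csv(dataset: LandmarkDataset, path) -> None:
    frame = dataset.meta.copy()
    flat = dataset.coords.reshape(dataset.n_specimens, -1)
    for j, col in enumerate(_coordinate_columns(dataset.k)):
        frame[col] = flat[:, j]
    frame.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_landmarks(path, format: str | None = None) -> LandmarkDataset:
    """Read a landmark dataset from a TPS or CSV file.

    ``format`` is inferred from the file extension when not given.
    """
    format = format or ("tps" if str(path).lower().endswith(".tps") else "csv")
    if format == "tps":
        with open(path, encoding="utf-8") as fh:
            return _parse_tps(fh.read())
    if format == "csv":
        return _parse_csv(path)
    raise ValueError(f"unknown format {format!r}")


def write_landmarks(dataset: LandmarkDataset, path,
                    format: str | None = None) -> None:
    """Write a dataset to ``path``; CSV round-trips coordinates exactly."""
    format = format or ("tps" if str(path).lower().endswith(".tps") else "csv")
    if format == "tps":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_write_tps(dataset))
    elif format == "csv":
        _write_csv(dataset, path)
    else:
        raise ValueError(f"unknown format {format!r}")


@dataclass
class ValidationReport:
    """Outcome of the study-design checks on a landmark dataset."""
    species_summary: pd.DataFrame
    failing_species: list = field(default_factory=list)
    duplicate_landmarks: list = field(default_factory=list)
    min_sites_per_species: int = 3

    @property
    def passed(self) -> bool:
        return not self.failing_species

    def __str__(self) -> str:
        lines = [self.species_summary.to_string()]
        if self.failing_species:
            lines.append(
                f"species below {self.min_sites_per_species} sites: "
                + ", ".join(self.failing_species))
        for spec_id, pairs in self.duplicate_landmarks:
            lines.append(
                f"warning: specimen {spec_id} has coincident landmarks "
                + ", ".join(f"{a + 1}/{b + 1}" for a, b in pairs))
        lines.append("PASS" if self.passed else "FAIL")
        return "\n".join(lines)


def validate_dataset(dataset: LandmarkDataset,
                     min_sites_per_species: int = 3) -> ValidationReport:
    """Check the sampling design: specimen and site counts per species.

    The study design requires every species to be sampled from at least
    ``min_sites_per_species`` distinct sites so that within-species shape
    variation is not underestimated.  Exactly coincident landmark pairs
    within a configuration are reported as digitization warnings.  The
    dataset is never mutated.
    """
    meta = dataset.meta
    grouped = meta.groupby("species", sort=True)
    summary = pd.DataFrame({
        "n_specimens": grouped.size(),
        "n_sites": grouped["site"].nunique(),
    })
    failing = summary.index[
        summary["n_sites"] < min_sites_per_species].tolist()
    duplicates = []
    for i in range(dataset.n_specimens):
        cfg = dataset.coords[i]
        diff = cfg[:, None, :] - cfg[None, :, :]
        ties = np.argwhere(
            (np.abs(diff).max(axis=2) == 0) &
            np.triu(np.ones((dataset.k, dataset.k), bool), 1))
        if len(ties):
            duplicates.append((meta.at[i, "specimen_id"],
                               [tuple(t) for t in ties]))
    return ValidationReport(summary, failing, duplicates,
                            min_sites_per_species)
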
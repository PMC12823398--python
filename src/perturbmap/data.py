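"""Core data containers and file I/O.

The pipeline works on four objects:

* :class:`CountMatrix` -- sparse spot x feature integer counts ``D[s, f]``,
  with a feature table distinguishing perturbation barcodes from endogenous
  genes.
* :class:`SpotTable` -- per-spot metadata: physical coordinates in um, array
  row/col indices, platform, and total UMI count.
* :class:`BarcodeDesign` -- the plasmid -> barcode membership matrix
  ``B[g, b]`` (each plasmid carries one or more 50-nt capture barcodes).
* :class:`NoduleMap` -- the spot -> region assignment ``A[s, r]`` with region
  classes (tumour nodule, normal tissue, unassigned).

On disk, counts use the conventional 10X-style layout: a Matrix-Market triplet
file plus feature and spot TSV tables.  Nodule maps and designs are plain CSV
with documented headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import ConfigurationError, FormatError

PLATFORMS = ("manual", "cytassist")
REGION_CLASSES = ("nodule", "normal", "unassigned")

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
SPOTS_FILE = "spots.tsv"

SPOT_COLUMNS = ["spot_id", "x", "y", "sample_id", "platform", "row", "col", "total_umi"]


@dataclass
class SpotTable:
    """Per-spot metadata; one row per capture spot."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"spot table is missing columns: {missing}")
        dup = self.df.duplicated(subset=["sample_id", "spot_id"])
        if dup.any():
            raise FormatError("spot_id values are not unique within sample")
        bad = set(self.df["platform"]) - set(PLATFORMS)
        if bad:
            raise FormatError(f"unknown platform values: {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def spot_ids(self) -> np.ndarray:
        return self.df["spot_id"].to_numpy()

    def subset(self, mask: np.ndarray) -> "SpotTable":
        return SpotTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, spots x features.

    ``spot_ids`` optionally labels the rows so the matrix can be aligned with
    a :class:`NoduleMap` without relying on positional order.
    """

    matrix: sp.csr_matrix
    features: pd.DataFrame  # columns: feature_id, feature_kind
    spot_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.spot_ids is not None:
            self.spot_ids = np.asarray(self.spot_ids)
            if self.spot_ids.size != self.matrix.shape[0]:
                raise FormatError("spot_ids length does not match matrix rows")
        if "feature_id" not in self.features.columns:
            raise FormatError("feature table requires a feature_id column")
        if "feature_kind" not in self.features.columns:
            self.features = self.features.assign(feature_kind="gene")
        if self.features["feature_id"].duplicated().any():
            raise FormatError("feature_id values are not unique")
        if self.matrix.shape[1] != len(self.features):
            raise FormatError(
                f"matrix has {self.matrix.shape[1]} columns but "
                f"{len(self.features)} features"
            )
        data = self.matrix.data
        if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
            raise FormatError("count matrix entries must be non-negative integers")
        self.features = self.features.reset_index(drop=True)

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]

    @property
    def feature_ids(self) -> np.ndarray:
        return self.features["feature_id"].to_numpy()

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def subset_spots(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        ids = self.spot_ids[mask] if self.spot_ids is not None else None
        return CountMatrix(self.matrix[mask], self.features.copy(), ids)

    def subset_features(self, feature_ids) -> "CountMatrix":
        order = pd.Index(self.features["feature_id"])
        idx = order.get_indexer(feature_ids)
        if np.any(idx < 0):
            missing = [f for f, i in zip(feature_ids, idx) if i < 0]
            raise ConfigurationError(f"features absent from matrix: {missing}")
        return CountMatrix(
            sp.csr_matrix(self.matrix[:, idx]),
            self.features.iloc[idx].reset_index(drop=True),
            None if self.spot_ids is None else self.spot_ids.copy(),
        )


@dataclass
class BarcodeDesign:
    """Plasmid -> barcode membership ``B[g, b]``.

    ``membership`` is a plasmid x barcode 0/1 DataFrame; every barcode belongs
    to exactly one plasmid and every plasmid carries at least one barcode.
    ``sequences`` optionally maps barcode_id to its 50-nt capture sequence.
    """

    membership: pd.DataFrame
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        m = self.membership.to_numpy()
        if not np.isin(m, (0, 1)).all():
            raise FormatError("design membership must be 0/1")
        if np.any(m.sum(axis=1) < 1):
            raise FormatError("every plasmid needs at least one barcode")
        if np.any(m.sum(axis=0) != 1):
            raise FormatError("every barcode must belong to exactly one plasmid")
        if self.sequences is not None:
            for bc, seq in self.sequences.items():
                if len(seq) != 50 or set(seq) - set("ACGT"):
                    raise FormatError(
                        f"barcode {bc}: sequences must be 50-nt over ACGT"
                    )

    @property
    def plasmids(self) -> list[str]:
        return list(self.membership.index)

    @property
    def barcodes(self) -> list[str]:
        return list(self.membership.columns)

    @property
    def n_plasmids(self) -> int:
        return self.membership.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.membership.shape[1]

    def matrix(self) -> np.ndarray:
        """B[g, b] as a float array."""
        return self.membership.to_numpy(dtype=float)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "BarcodeDesign":
        """Build from a long table with columns plasmid_id, barcode_id[, sequence]."""
        for col in ("plasmid_id", "barcode_id"):
            if col not in table.columns:
                raise FormatError(f"design table requires column {col!r}")
        plasmids = list(dict.fromkeys(table["plasmid_id"]))
        barcodes = list(table["barcode_id"])
        member = pd.DataFrame(0, index=plasmids, columns=barcodes, dtype=int)
        for _, rec in table.iterrows():
            member.loc[rec["plasmid_id"], rec["barcode_id"]] = 1
        seqs = None
        if "sequence" in table.columns and table["sequence"].notna().all():
            seqs = dict(zip(table["barcode_id"], table["sequence"]))
        return cls(member, seqs)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BarcodeDesign":
        return cls.from_table(pd.read_csv(path))

    def to_table(self) -> pd.DataFrame:
        rows = []
        for bc in self.barcodes:
            plasmid = self.membership.index[self.membership[bc] == 1][0]
            rec = {"plasmid_id": plasmid, "barcode_id": bc}
            if self.sequences:
                rec["sequence"] = self.sequences.get(bc)
            rows.append(rec)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, index=False)


@dataclass
class NoduleMap:
    """Spot -> region assignment with region classes."""

    df: pd.DataFrame  # columns: spot_id, region_id, region_class

    def __post_init__(self) -> None:
        for col in ("spot_id", "region_id", "region_class"):
            if col not in self.df.columns:
                raise FormatError(f"nodule map requires column {col!r}")
        if self.df["spot_id"].duplicated().any():
            raise FormatError("a spot maps to more than one region")
        bad = set(self.df["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise FormatError(f"unknown region classes: {sorted(bad)}")
        classes = self.df.groupby("region_id")["region_class"].nunique()
        if (classes > 1).any():
            raise FormatError("a region carries more than one region class")
        self.df = self.df.reset_index(drop=True)

    @property
    def regions(self) -> pd.DataFrame:
        """One row per region: region_id, region_class, n_spots."""
        return (
            self.df.groupby(["region_id", "region_class"], sort=False)
            .size()
            .rename("n_spots")
            .reset_index()
        )

    def region_ids(self, region_class: str | None = None) -> list:
        reg = self.regions
        if region_class is not None:
            reg = reg[reg["region_class"] == region_class]
        return list(reg["region_id"])

    def membership_matrix(self, spot_ids: np.ndarray, region_ids: list) -> np.ndarray:
        """A[s, r] over the given spot ordering; rows of unmapped spots are zero."""
        assign = dict(zip(self.df["spot_id"], self.df["region_id"]))
        col = {r: j for j, r in enumerate(region_ids)}
        A = np.zeros((len(spot_ids), len(region_ids)))
        for i, s in enumerate(spot_ids):
            r = assign.get(s)
            if r is not None and r in col:
                A[i, col[r]] = 1.0
        return A

    @classmethod
    def from_csv(cls, path: str | Path) -> "NoduleMap":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# count-matrix directory I/O (10X-style: matrix.mtx + features.tsv + spots.tsv)
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path) -> tuple[CountMatrix, SpotTable]:
    """Read a counts directory: Matrix-Market triplets + feature/spot TSVs.

    Returns the counts (spots x features) and the spot table with
    ``total_umi`` populated from the matrix row sums.
    """
    path = Path(path)
    for fname in (MATRIX_FILE, FEATURES_FILE, SPOTS_FILE):
        if not (path / fname).exists():
            raise FormatError(f"missing file: {path / fname}")
    try:
        mat = sp.csr_matrix(mmread(path / MATRIX_FILE))
    except Exception as exc:  # malformed header / triplets
        raise FormatError(f"cannot parse {path / MATRIX_FILE}: {exc}") from exc
    features = pd.read_csv(path / FEATURES_FILE, sep="\t")
    spots_df = pd.read_csv(path / SPOTS_FILE, sep="\t")
    if mat.shape[1] != len(features):
        raise FormatError(
            f"{path / MATRIX_FILE} has {mat.shape[1]} columns but "
            f"{path / FEATURES_FILE} lists {len(features)} features"
        )
    if mat.shape[0] != len(spots_df):
        raise FormatError(
            f"{path / MATRIX_FILE} has {mat.shape[0]} rows but "
            f"{path / SPOTS_FILE} lists {len(spots_df)} spots"
        )
    if mat.data.size and np.any(mat.data != np.floor(mat.data)):
        raise FormatError(f"{path / MATRIX_FILE} contains non-integer entries")
    counts = CountMatrix(mat, features, spots_df["spot_id"].to_numpy())
    spots_df = spots_df.assign(total_umi=counts.row_sums().astype(int))
    return counts, SpotTable(spots_df)


def write_count_matrix(path: str | Path, counts: CountMatrix, spots: SpotTable) -> None:
    """Write the directory layout read by :func:`read_count_matrix`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coo = counts.matrix.tocoo()
    mmwrite(str(path / MATRIX_FILE), coo, field="integer")
    counts.features.to_csv(path / FEATURES_FILE, sep="\t", index=False)
    spots.df.to_csv(path / SPOTS_FILE, sep="\t", index=False)
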
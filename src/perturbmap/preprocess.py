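"""Spot and barcode preprocessing filters.

The filters reproduce the standard quality steps applied before genotyping:

* spots must exceed 5,000 total UMIs (strict), and on CytAssist arrays the
  outermost ring of spots is removed first (it shows inflated counts);
* barcodes whose average log1p expression per 1e4 counts falls below 0.05
  across all spots of all samples are flagged as low-signal;
* unassigned spots at least a minimum physical distance (250-700 um) from the
  nearest tumour spot are grouped into one "normal tissue" region per sample.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .data import BarcodeDesign, CountMatrix, NoduleMap, SpotTable
from .errors import ConfigurationError, EmptyResultError


def split_features(
    counts: CountMatrix, design: BarcodeDesign
) -> tuple[CountMatrix, CountMatrix]:
    """Partition the feature columns into (barcode block, gene block).

    The barcode block has exactly the design's barcodes, in design order; the
    gene block keeps every remaining feature in its original order.
    """
    feature_index = pd.Index(counts.features["feature_id"])
    missing = [b for b in design.barcodes if b not in feature_index]
    if missing:
        raise ConfigurationError(f"design barcodes absent from features: {missing}")
    barcode_counts = counts.subset_features(design.barcodes)
    barcode_counts.features["feature_kind"] = "barcode"
    gene_mask = ~feature_index.isin(design.barcodes)
    gene_counts = counts.subset_features(feature_index[gene_mask])
    return barcode_counts, gene_counts


def filter_spots(
    counts: CountMatrix, spots: SpotTable, config: PipelineConfig | None = None
) -> tuple[CountMatrix, SpotTable]:
    """Apply the ring exclusion (CytAssist only) and the strict UMI filter.

    Ring exclusion runs first: for each CytAssist sample, spots whose array
    row or column equals the per-sample min or max are dropped.  Then spots
    with ``total_umi`` <= the threshold (default 5,000) are dropped.  The
    returned spot table carries a ``ring_excluded`` marker column so that
    re-applying the filter never strips a second perimeter (the operation is
    idempotent).
    """
    config = config or PipelineConfig()
    df = spots.df
    already = df["ring_excluded"].to_numpy(dtype=bool) \
        if "ring_excluded" in df.columns else np.zeros(len(df), dtype=bool)
    keep_ring = np.ones(len(df), dtype=bool)
    for sample_id, sub in df.groupby("sample_id"):
        if sub["platform"].iloc[0] != "cytassist" or already[sub.index].all():
            continue
        rim = (
            (sub["row"] == sub["row"].min())
            | (sub["row"] == sub["row"].max())
            | (sub["col"] == sub["col"].min())
            | (sub["col"] == sub["col"].max())
        )
        keep_ring[sub.index[rim]] = False
    n_ring = int((~keep_ring).sum())
    keep_umi = df["total_umi"].to_numpy() > config.umi_threshold
    keep = keep_ring & keep_umi
    n_umi = int((keep_ring & ~keep_umi).sum())
    if not keep.any():
        raise EmptyResultError(
            f"all spots removed (ring exclusion: {n_ring}, "
            f"UMI <= {config.umi_threshold}: {n_umi})"
        )
    out_spots = spots.subset(keep)
    out_spots.df["ring_excluded"] = True
    return counts.subset_spots(keep), out_spots


def flag_low_signal_barcodes(
    barcode_counts: CountMatrix,
    spots: SpotTable,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag barcodes with insufficient signal pooled across all spots/samples.

    For every barcode, counts are scaled per spot to 1e4 total UMIs,
    log1p-transformed, and averaged over all spots; barcodes whose average is
    below ``threshold`` are flagged.  Spots with zero total UMIs are excluded
    from the average with a warning.

    Returns a table with columns barcode_id, mean_log1p_per_1e4, keep.
    """
    totals = spots.df["total_umi"].to_numpy(dtype=float)
    ok = totals > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} zero-total spots from the "
            "low-signal average"
        )
    dense = barcode_counts.dense()[ok]
    scaled = dense * (1e4 / totals[ok])[:, None]
    mean_log1p = np.log1p(scaled).mean(axis=0) if dense.size else np.zeros(dense.shape[1])
    return pd.DataFrame(
        {
            "barcode_id": barcode_counts.feature_ids,
            "mean_log1p_per_1e4": mean_log1p,
            "keep": mean_log1p >= threshold,
        }
    )


def annotate_normal_spots(
    spots: SpotTable,
    nodule_map: NoduleMap,
    min_distance: float = 500.0,
    allowed_range: tuple[float, float] = (250.0, 700.0),
) -> NoduleMap:
    """Add one normal-tissue region per sample to the nodule map.

    Candidate spots are those not assigned to any region whose Euclidean
    distance (um) to the nearest tumour spot of the same sample is at least
    ``min_distance``.
    """
    if not allowed_range[0] <= min_distance <= allowed_range[1]:
        raise ConfigurationError(
            f"min_distance {min_distance} outside allowed range {allowed_range}"
        )
    df = spots.df
    assigned = set(nodule_map.df["spot_id"])
    nodule_spots = set(
        nodule_map.df.loc[nodule_map.df["region_class"] == "nodule", "spot_id"]
    )
    new_rows = []
    for sample_id, sub in df.groupby("sample_id"):
        tumour = sub[sub["spot_id"].isin(nodule_spots)]
        free = sub[~sub["spot_id"].isin(assigned)]
        if tumour.empty or free.empty:
            continue
        tree = cKDTree(tumour[["x", "y"]].to_numpy())
        dist, _ = tree.query(free[["x", "y"]].to_numpy())
        qualify = free.loc[dist >= min_distance, "spot_id"]
        if qualify.empty:
            warnings.warn(f"sample {sample_id}: no qualifying normal spots")
            continue
        region_id = f"normal_{sample_id}"
        new_rows.extend(
            {"spot_id": s, "region_id": region_id, "region_class": "normal"}
            for s in qualify
        )
    if not new_rows:
        warnings.warn("no normal regions could be annotated")
        return NoduleMap(nodule_map.df.copy())
    combined = pd.concat([nodule_map.df, pd.DataFrame(new_rows)], ignore_index=True)
    return NoduleMap(combined)
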
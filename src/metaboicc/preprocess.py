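"""Feature-level quality filters, LOD definition, and annotation matching.

The preprocessing chain for an untargeted LC-HRMS feature table:

1. blank filter — drop features that are present in *every* blank sample
   unless their representative study-sample intensity is at least
   ``fold`` (default 5) times the representative blank intensity;
2. detection filter — keep features detected in at least 40% of samples;
3. LOD — per feature, the lowest detected intensity (nondetects are treated
   as left-censored at this value by the model);
4. annotation — match features to a database of known-detectable compounds
   by accurate mass (+-10 ppm against the database mass) and retention time
   (+-0.15 min), ranked by combined closeness;
5. duplicate collapse — when several features map to the same compound
   (adducts, isomers, algorithm duplicates), report only the feature with
   the highest posterior-median ICC.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = [
    "blank_filter",
    "detection_filter",
    "compute_lod",
    "annotate",
    "collapse_duplicates",
]


def blank_filter(
    table: FeatureTable,
    blank_table: FeatureTable,
    fold: float = 5.0,
    stat: str = "median",
) -> tuple[FeatureTable, pd.DataFrame]:
    """Remove features present in every blank unless enriched in samples.

    A feature is removed when (a) it is detected in *every* blank sample and
    (b) its representative sample intensity is below ``fold`` times its
    representative blank intensity. The representative statistic (over
    detected values) is the median by default; ``stat='mean'`` is accepted.

    Returns the filtered table and a per-feature disposition report
    (columns: ``in_all_blanks``, ``sample_stat``, ``blank_stat``, ``ratio``,
    ``kept``, ``reason``).
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    shared = table.feature_ids.intersection(blank_table.feature_ids)
    if len(shared) == 0:
        raise ValueError("blank table shares no feature ids with the sample table")

    agg = np.median if stat == "median" else np.mean
    rows = []
    for fid in table.feature_ids:
        if fid not in shared:
            rows.append((fid, False, np.nan, np.nan, np.nan, True, "absent from blank table"))
            continue
        bvals = blank_table.intensities[fid]
        if not bool(bvals.notna().all()):
            rows.append((fid, False, np.nan, np.nan, np.nan, True, "not in every blank"))
            continue
        svals = table.intensities[fid].dropna().to_numpy()
        s_stat = float(agg(svals)) if len(svals) else 0.0
        b_stat = float(agg(bvals.to_numpy()))
        ratio = s_stat / b_stat if b_stat > 0 else np.inf
        kept = ratio >= fold
        reason = "enriched >= fold in samples" if kept else "blank-dominated"
        rows.append((fid, True, s_stat, b_stat, ratio, kept, reason))
    report = pd.DataFrame(
        rows,
        columns=["feature_id", "in_all_blanks", "sample_stat", "blank_stat", "ratio", "kept", "reason"],
    ).set_index("feature_id")
    kept_ids = report.index[report["kept"]]
    return table.subset(kept_ids), report


def detection_filter(
    table: FeatureTable, min_rate: float = 0.40
) -> tuple[FeatureTable, pd.DataFrame]:
    """Keep features detected in at least ``min_rate`` of samples (>= compare).

    Idempotent: reapplying with the same threshold changes nothing.
    """
    if not 0.0 < min_rate <= 1.0:
        raise ValueError("min_rate must be in (0, 1]")
    rates = table.detection_rates()
    kept = rates >= min_rate
    report = pd.DataFrame({"detection_rate": rates, "kept": kept})
    report.index.name = "feature_id"
    return table.subset(rates.index[kept]), report


def compute_lod(table: FeatureTable) -> pd.DataFrame:
    """Per-feature LOD (lowest detected intensity) and detection rate.

    Raises if any feature has no detected value (its LOD is undefined).
    """
    ints = table.intensities
    n_det = ints.notna().sum(axis=0)
    empty = n_det.index[n_det == 0]
    if len(empty):
        raise ValueError(
            f"{len(empty)} features have no detected values, e.g. {list(empty[:3])}"
        )
    qc = pd.DataFrame(
        {
            "detection_rate": ints.notna().mean(axis=0),
            "lod": ints.min(axis=0, skipna=True),
            "n_detected": n_det,
        }
    )
    qc.index.name = "feature_id"
    return qc


def annotate(
    table: FeatureTable,
    db: pd.DataFrame,
    ppm_tol: float = 10.0,
    rt_tol: float = 0.15,
    max_matches: int = 10,
) -> pd.DataFrame:
    """Match features to an annotation database by mass and retention time.

    A database entry matches a feature when ``|mass_f - mass_db| / mass_db *
    1e6 <= ppm_tol`` and ``|rt_f - rt_db| <= rt_tol``. Matches are ranked
    per feature by the combined normalised closeness score
    ``|dppm|/ppm_tol + |drt|/rt_tol`` (smaller is better), keeping at most
    ``max_matches``. Features lacking mass or RT metadata are skipped with
    a warning.

    Parameters
    ----------
    db
        DataFrame with columns ``name``, ``mass`` (Da), ``rt`` (min), plus
        any extra columns (e.g. ``compound_class``, ``pathways``) carried
        into the output.

    Returns
    -------
    Long DataFrame: one row per (feature, matched compound) with ppm / RT
    errors, score and rank.
    """
    for col in ("name", "mass", "rt"):
        if col not in db.columns:
            raise ValueError(f"annotation database lacks required column '{col}'")
    if table.features is None:
        raise ValueError("feature table carries no mass/RT metadata")
    feats = table.features
    extra_cols = [c for c in db.columns if c not in ("name", "mass", "rt")]

    db_mass = db["mass"].to_numpy(dtype=float)
    db_rt = db["rt"].to_numpy(dtype=float)
    out = []
    skipped = []
    for fid in table.feature_ids:
        row = feats.loc[fid]
        mass, rt = row.get("mass", np.nan), row.get("rt", np.nan)
        if not (np.isfinite(mass) and np.isfinite(rt)):
            skipped.append(fid)
            continue
        dppm = np.abs(mass - db_mass) / db_mass * 1e6
        drt = np.abs(rt - db_rt)
        ok = (dppm <= ppm_tol) & (drt <= rt_tol)
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        score = dppm[idx] / ppm_tol + drt[idx] / rt_tol
        order = np.argsort(score, kind="stable")[:max_matches]
        for rank, j in enumerate(order, start=1):
            i = idx[j]
            rec = {
                "feature_id": fid,
                "name": db["name"].iloc[i],
                "ppm_error": float(dppm[i]),
                "rt_error": float(drt[i]),
                "score": float(score[j]),
                "rank": rank,
            }
            for c in extra_cols:
                rec[c] = db[c].iloc[i]
            out.append(rec)
    if skipped:
        warnings.warn(
            f"{len(skipped)} features lack mass/RT metadata and were skipped, "
            f"e.g. {skipped[:3]}",
            stacklevel=2,
        )
    return pd.DataFrame(
        out, columns=["feature_id", "name", "ppm_error", "rt_error", "score", "rank", *extra_cols]
    )


def collapse_duplicates(
    icc_results: pd.DataFrame, annotation: pd.DataFrame | pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One result per compound: keep the feature with the highest median ICC.

    Parameters
    ----------
    icc_results
        Per-feature results indexed by feature id with at least an ``icc``
        column; ``icc_low`` / ``icc_high`` are used for tie-breaking when
        present (narrower credible interval wins, then lexicographic id).
    annotation
        Mapping feature id -> compound name: either a Series, or a DataFrame
        with ``feature_id`` and ``name`` columns (e.g. rank-1 rows of
        :func:`annotate`).

    Returns
    -------
    (per_compound, dropped)
        ``per_compound``: one row per unique compound (indexed by compound
        name, with the winning ``feature_id`` as a column). ``dropped``:
        the annotated features that lost the comparison.
    """
    if isinstance(annotation, pd.DataFrame):
        mapping = annotation.set_index("feature_id")["name"]
    else:
        mapping = annotation
    mapping = mapping[~mapping.index.duplicated(keep="first")]

    fitted = mapping.index.intersection(icc_results.index)
    lost = mapping.index.difference(icc_results.index)
    if len(lost):
        orphans = sorted(set(mapping.loc[lost]) - set(mapping.loc[fitted]))
        if orphans:
            warnings.warn(
                f"{len(orphans)} compounds have no fitted feature and are omitted, "
                f"e.g. {orphans[:3]}",
                stacklevel=2,
            )
    sub = icc_results.loc[fitted].copy()
    sub["compound"] = mapping.loc[fitted]
    if "icc_low" in sub.columns and "icc_high" in sub.columns:
        sub["_ci_width"] = sub["icc_high"] - sub["icc_low"]
    else:
        sub["_ci_width"] = 0.0
    sub = sub.rename_axis("feature_id").reset_index()
    sub = sub.sort_values(
        by=["compound", "icc", "_ci_width", "feature_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    winners = sub.groupby("compound", sort=True).head(1)
    dropped = sub.loc[~sub.index.isin(winners.index)].drop(columns="_ci_width")
    per_compound = winners.drop(columns="_ci_width").set_index("compound")
    return per_compound, dropped.set_index("feature_id")
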
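"""Validation statistics over a chromatin-state segmentation.

All statistics are segment-based: the unit of observation is the fixed-width
(default 200 bp) genomic segment, matching the resolution of the annotation
itself.  A segment overlaps a feature when at least one base intersects.
Fold enrichment compares observed overlap counts to the expectation under a
uniform scatter of the feature across segments, reported as log2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hmm_core import StateAnnotation
from .tracks_io import FeatureIntervals


@dataclass
class SnpSet:
    """SNP records: chromosome, 0-based position, phenotype, optional MAF."""

    table: pd.DataFrame  # columns: chrom, pos, phenotype[, maf]

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "phenotype"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"SNP table missing columns: {sorted(missing)}")
        if "maf" in self.table.columns:
            maf = self.table["maf"].dropna()
            if ((maf < 0) | (maf > 0.5)).any():
                raise ValueError("MAF values must lie in [0, 0.5]")

    @staticmethod
    def read(path) -> "SnpSet":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        return SnpSet(df)


def read_scores(path) -> pd.DataFrame:
    """Per-base conservation scores: tab-separated chrom, pos, score."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return df


def _overlap_mask(
    ann: StateAnnotation, feats: FeatureIntervals
) -> dict[str, np.ndarray]:
    """Boolean per-segment mask: does the segment intersect any feature base?"""
    w = ann.segment_width
    masks = {c: np.zeros(lab.size, dtype=bool) for c, lab in ann.labels.items()}
    for chrom, arr in feats.by_chromosome().items():
        if chrom not in masks:
            continue
        mask = masks[chrom]
        for start, end in arr:
            lo = max(int(start) // w, 0)
            hi = min(-(-int(end) // w), mask.size)
            if hi > lo:
                mask[lo:hi] = True
    return masks


def _flat_labels(ann: StateAnnotation) -> np.ndarray:
    return np.concatenate([ann.labels[c] for c in ann.labels])


def fold_enrichment(ann: StateAnnotation, feats: FeatureIntervals) -> pd.DataFrame:
    """Per-state observed/expected segment overlap with one feature set.

    expected = (segments in state / total segments) * total overlapping
    segments; log2FE = log2(observed / expected), NaN when expected is 0.
    States absent from the annotation get a zero row with ``flag='absent'``.
    """
    masks = _overlap_mask(ann, feats)
    labels = _flat_labels(ann)
    overlap = np.concatenate([masks[c] for c in ann.labels])
    total = labels.size
    total_overlap = int(overlap.sum())
    rows = []
    for state in range(1, ann.n_states + 1):
        in_state = labels == state
        n_state = int(in_state.sum())
        observed = int((in_state & overlap).sum())
        expected = (n_state / total) * total_overlap if total else 0.0
        if expected > 0 and observed > 0:
            log2fe = math.log2(observed / expected)
        elif expected > 0:
            log2fe = float("-inf")
        else:
            log2fe = float("nan")
        rows.append(
            {
                "state": state,
                "feature": feats.name,
                "n_segments": n_state,
                "observed": observed,
                "expected": expected,
                "log2_fold_enrichment": log2fe,
                "flag": "absent" if n_state == 0 else "",
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["total_segments"] = total
    df.attrs["total_overlapping_segments"] = total_overlap
    return df


def precision_recall(
    ann: StateAnnotation,
    states_subset: Sequence[int],
    feats: FeatureIntervals,
) -> tuple[float, float]:
    """Segment-level precision and element-level recall for a state subset.

    precision: fraction of predicted segments (labeled with any state in the
    subset) that overlap a feature.  recall: fraction of feature elements
    overlapped by at least one predicted segment.  An empty prediction yields
    precision NaN, recall 0.
    """
    if not states_subset:
        raise ValueError("states_subset is empty")
    subset = set(int(s) for s in states_subset)
    masks = _overlap_mask(ann, feats)
    w = ann.segment_width

    n_pred = 0
    n_pred_overlap = 0
    pred_masks = {}
    for chrom, lab in ann.labels.items():
        pred = np.isin(lab, list(subset))
        pred_masks[chrom] = pred
        n_pred += int(pred.sum())
        n_pred_overlap += int((pred & masks[chrom]).sum())
    precision = n_pred_overlap / n_pred if n_pred else float("nan")

    n_feat = 0
    n_feat_hit = 0
    for chrom, start, end in feats.intervals:
        n_feat += 1
        if chrom not in pred_masks:
            continue
        lo = max(start // w, 0)
        hi = min(-(-end // w), pred_masks[chrom].size)
        if hi > lo and pred_masks[chrom][lo:hi].any():
            n_feat_hit += 1
    recall = n_feat_hit / n_feat if n_feat else float("nan")
    return precision, recall


def tss_distance_profile(
    ann: StateAnnotation,
    tss: FeatureIntervals,
    window: int = 5000,
    exclude_no_tss_chroms: bool = False,
) -> pd.DataFrame:
    """Signed distance from each segment midpoint to the nearest TSS, by state.

    TSS intervals are treated as points at their midpoints.  Reports per
    state the count, median |distance| and the fraction of segments within
    ``window`` bases of a TSS.  Segments on chromosomes without any TSS have
    infinite distance; they count in the fraction's denominator unless
    ``exclude_no_tss_chroms``.
    """
    w = ann.segment_width
    tss_points = {
        chrom: np.sort((arr[:, 0] + arr[:, 1]) // 2)
        for chrom, arr in tss.by_chromosome().items()
    }
    dists = []
    labs = []
    for chrom, lab in ann.labels.items():
        mids = np.arange(lab.size, dtype=np.int64) * w + w // 2
        pts = tss_points.get(chrom)
        if pts is None or pts.size == 0:
            if exclude_no_tss_chroms:
                continue
            d = np.full(lab.size, np.inf)
        else:
            idx = np.searchsorted(pts, mids)
            left = pts[np.clip(idx - 1, 0, pts.size - 1)]
            right = pts[np.clip(idx, 0, pts.size - 1)]
            d_left = mids - left
            d_right = mids - right
            d = np.where(np.abs(d_left) <= np.abs(d_right), d_left, d_right).astype(float)
            d[idx == 0] = d_right[idx == 0]
            d[idx == pts.size] = d_left[idx == pts.size]
        dists.append(d)
        labs.append(lab)
    dist = np.concatenate(dists)
    labels = np.concatenate(labs)
    rows = []
    for state in range(1, ann.n_states + 1):
        d = dist[labels == state]
        finite = d[np.isfinite(d)]
        rows.append(
            {
                "state": state,
                "n_segments": int(d.size),
                "median_abs_distance": float(np.median(np.abs(finite))) if finite.size else float("nan"),
                "fraction_within_window": float((np.abs(d) <= window).sum() / d.size) if d.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _snp_states(ann: StateAnnotation, snps: SnpSet) -> np.ndarray:
    """State label (0 = off-annotation) for each SNP."""
    w = ann.segment_width
    out = np.zeros(len(snps.table), dtype=np.int64)
    for i, (chrom, pos) in enumerate(zip(snps.table["chrom"], snps.table["pos"])):
        lab = ann.labels.get(chrom)
        if lab is None:
            continue
        seg = int(pos) // w
        if 0 <= seg < lab.size:
            out[i] = lab[seg]
    return out


def gwas_enrichment(
    ann: StateAnnotation,
    snps: SnpSet,
    per_phenotype: bool = False,
    test_states: Sequence[int] | None = None,
    min_snps: int = 10,
    mask: FeatureIntervals | None = None,
) -> dict:
    """SNP enrichment per chromatin state, with an overall chi-square test.

    Per state (and optionally per phenotype, keeping only phenotypes with at
    least ``min_snps`` SNPs): log2 fold enrichment of the SNP count against
    an expectation proportional to the state's fraction of segments.  The
    overall test is the classical (uncorrected) chi-square on the 2x2 table
    (inside/outside ``test_states``) x (SNPs / genome segments); underflowed
    p-values are reported as 0.  ``mask`` removes SNPs in excluded regions
    (e.g. the major-histocompatibility region) before counting.

    Per phenotype the most highly enriched state is the argmax of log2FE,
    ties broken toward more overlapping SNPs, then the lower state index.
    """
    table = snps.table
    if mask is not None:
        masked = np.zeros(len(table), dtype=bool)
        by_chrom = mask.by_chromosome()
        for i, (chrom, pos) in enumerate(zip(table["chrom"], table["pos"])):
            arr = by_chrom.get(chrom)
            if arr is not None and ((arr[:, 0] <= pos) & (pos < arr[:, 1])).any():
                masked[i] = True
        table = table.loc[~masked].reset_index(drop=True)
    working = SnpSet(table)
    states = _snp_states(ann, working)
    labels = _flat_labels(ann)
    total_segments = labels.size
    n_states = ann.n_states
    state_frac = np.array(
        [(labels == s).sum() / total_segments for s in range(1, n_states + 1)]
    )

    def _state_table(snp_states: np.ndarray) -> pd.DataFrame:
        n = snp_states.size
        rows = []
        for s in range(1, n_states + 1):
            observed = int((snp_states == s).sum())
            expected = n * state_frac[s - 1]
            if expected > 0 and observed > 0:
                fe = math.log2(observed / expected)
            elif expected > 0:
                fe = float("-inf")
            else:
                fe = float("nan")
            rows.append(
                {"state": s, "observed": observed, "expected": expected,
                 "log2_fold_enrichment": fe}
            )
        return pd.DataFrame(rows)

    result: dict = {"per_state": _state_table(states)}

    if test_states is None:
        fe = result["per_state"]["log2_fold_enrichment"].to_numpy()
        test_states = [int(np.nanargmax(np.where(np.isfinite(fe), fe, -np.inf))) + 1]
    test_set = set(int(s) for s in test_states)
    snp_in = int(np.isin(states, list(test_set)).sum())
    snp_out = states.size - snp_in
    seg_in = int(np.isin(labels, list(test_set)).sum())
    seg_out = total_segments - seg_in
    contingency = np.array([[snp_in, snp_out], [seg_in, seg_out]], dtype=float)
    if contingency.sum(axis=1).all() and contingency.sum(axis=0).all():
        chi2, p, _, _ = stats.chi2_contingency(contingency, correction=False)
    else:
        chi2, p = float("nan"), float("nan")
    result["chi2"] = {
        "states": sorted(test_set),
        "statistic": float(chi2),
        "p_value": 0.0 if (p == 0 or p < 5e-324) else float(p),
        "table": contingency,
    }

    if per_phenotype:
        pheno_rows = []
        argmax_rows = []
        counts = working.table["phenotype"].value_counts()
        kept = counts[counts >= min_snps].index
        for pheno in kept:
            sel = (working.table["phenotype"] == pheno).to_numpy()
            sub = _state_table(states[sel])
            sub.insert(0, "phenotype", pheno)
            pheno_rows.append(sub)
            fe = sub["log2_fold_enrichment"].to_numpy()
            obs = sub["observed"].to_numpy()
            finite = np.where(np.isfinite(fe), fe, -np.inf)
            best = np.lexsort((sub["state"].to_numpy(), -obs, -finite))[0]
            argmax_rows.append(
                {"phenotype": pheno, "best_state": int(sub["state"].iloc[best]),
                 "log2_fold_enrichment": float(fe[best]), "n_snps": int(sel.sum())}
            )
        result["per_phenotype"] = (
            pd.concat(pheno_rows, ignore_index=True) if pheno_rows else pd.DataFrame()
        )
        result["most_enriched_state"] = pd.DataFrame(argmax_rows)
        result["n_phenotypes_excluded"] = int((counts < min_snps).sum())
    return result


def conservation_summary(
    ann: StateAnnotation,
    snps: SnpSet | None = None,
    scores: pd.DataFrame | None = None,
    maf_retain: float = 0.01,
    maf_low: float = 0.1,
    compare_states: tuple[int, int] | None = None,
) -> dict:
    """Selective-constraint summaries per chromatin state.

    Population-genetic level: among SNPs with MAF >= ``maf_retain`` (very
    rare variants mostly reflect mutation, not selection), the fraction with
    MAF < ``maf_low`` per state — higher fractions indicate stronger negative
    selection.  Cross-species level: mean per-segment conservation score,
    where a segment's score is the mean over its bases.  ``compare_states``
    adds a Mann-Whitney U test between two states' SNP MAF sets.
    """
    result: dict = {}
    maf_by_state: dict[int, np.ndarray] = {}
    if snps is not None:
        if "maf" not in snps.table.columns:
            raise ValueError("SNP table has no 'maf' column")
        keep = snps.table["maf"] >= maf_retain
        retained = SnpSet(snps.table.loc[keep].reset_index(drop=True))
        states = _snp_states(ann, retained)
        maf = retained.table["maf"].to_numpy()
        rows = []
        for s in range(1, ann.n_states + 1):
            vals = maf[states == s]
            maf_by_state[s] = vals
            rows.append(
                {
                    "state": s,
                    "n_snps": int(vals.size),
                    "fraction_low_maf": float((vals < maf_low).mean()) if vals.size else float("nan"),
                    "flag": "no_snps" if vals.size == 0 else "",
                }
            )
        result["maf"] = pd.DataFrame(rows)

    if scores is not None:
        w = ann.segment_width
        seg_means: dict[int, list[float]] = {s: [] for s in range(1, ann.n_states + 1)}
        for chrom, grp in scores.groupby("chrom"):
            lab = ann.labels.get(chrom)
            if lab is None:
                continue
            seg = grp["pos"].to_numpy() // w
            ok = (seg >= 0) & (seg < lab.size)
            per_seg = pd.Series(grp["score"].to_numpy()[ok]).groupby(seg[ok]).mean()
            for seg_idx, val in per_seg.items():
                seg_means[int(lab[int(seg_idx)])].append(float(val))
        rows = []
        for s in range(1, ann.n_states + 1):
            vals = seg_means.get(s, [])
            rows.append(
                {
                    "state": s,
                    "n_segments_scored": len(vals),
                    "mean_score": float(np.mean(vals)) if vals else float("nan"),
                }
            )
        result["scores"] = pd.DataFrame(rows)

    if compare_states is not None:
        a, b = compare_states
        va, vb = maf_by_state.get(a), maf_by_state.get(b)
        if va is None or vb is None or not va.size or not vb.size:
            result["mannwhitney"] = {"states": (a, b), "p_value": float("nan")}
        else:
            stat = stats.mannwhitneyu(va, vb, alternative="two-sided")
            result["mannwhitney"] = {
                "states": (a, b),
                "statistic": float(stat.statistic),
                "p_value": float(stat.pvalue),
            }
    return result
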
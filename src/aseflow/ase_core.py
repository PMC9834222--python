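"""Folded ASE score, homozygosity-threshold calibration, and locus filtering.

The ASE score folds the allelic fraction around 0.5::

    score = |ref / (ref + alt) - 0.5| + 0.5

so 0.5 means perfectly balanced expression and 1.0 monoallelic
expression, regardless of which allele is the major one. Genuinely
homozygous loci leak into RNA-seq allele counts as near-1.0 scores
(sequencing error on the silent allele); samples with known genotypes
are used to calibrate a score threshold separating true heterozygous
loci from these artifacts via ROC analysis and Youden's J, with balanced
resampling to undo the large het/hom class imbalance. Non-genotyped
samples are then filtered with that threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from aseflow.io_formats import ZYGOSITY_HET, ZYGOSITY_HOM

logger = logging.getLogger(__name__)

# sentinel offset placing one ROC candidate below all scores (=> call
# everything homozygous) and one above all scores (=> call nothing)
_SENTINEL_OFFSET = 0.01


class CalibrationError(ValueError):
    """Threshold calibration is impossible (e.g. an empty class)."""


@dataclass
class ThresholdEstimate:
    """Calibrated homozygosity cutoff plus resampling/ROC diagnostics.

    Attributes
    ----------
    threshold
        Arithmetic mean of the per-resample Youden-optimal thresholds;
        scores >= threshold are called homozygous.
    per_resample_thresholds
        One Youden-optimal threshold per balanced resample.
    n_het, n_hom
        Calibration class sizes before downsampling.
    roc_points
        ROC over the full (un-resampled) calibration set: columns
        ``fpr``, ``tpr``, ``threshold``.
    """

    threshold: float
    per_resample_thresholds: np.ndarray
    n_resamples: int
    n_het: int
    n_hom: int
    roc_points: pd.DataFrame = field(repr=False)

    def to_json(self, path) -> None:
        payload = {
            "threshold": self.threshold,
            "n_resamples": self.n_resamples,
            "n_het": self.n_het,
            "n_hom": self.n_hom,
            "per_resample_thresholds": [float(t) for t in self.per_resample_thresholds],
            "roc_points": {
                "fpr": self.roc_points["fpr"].tolist(),
                "tpr": self.roc_points["tpr"].tolist(),
                "threshold": self.roc_points["threshold"].tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "ThresholdEstimate":
        payload = json.loads(Path(path).read_text())
        return cls(
            threshold=payload["threshold"],
            per_resample_thresholds=np.asarray(payload["per_resample_thresholds"]),
            n_resamples=payload["n_resamples"],
            n_het=payload["n_het"],
            n_hom=payload["n_hom"],
            roc_points=pd.DataFrame(payload["roc_points"]),
        )


def compute_ase_score(ref_count, alt_count):
    """Fold the reference-allele fraction into an ASE score in [0.5, 1].

    ``score = |ref / (ref + alt) - 0.5| + 0.5``; symmetric under swapping
    the two counts. Accepts scalars or arrays; raises on zero total depth.

    Evaluated as ``max(ref, alt) / (ref + alt)``, which is algebraically
    identical to the folded form but exactly swap-symmetric in floating
    point.
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    total = ref + alt
    if np.any(total < 1):
        raise ValueError("ref_count + alt_count must be >= 1")
    score = np.maximum(ref, alt) / total
    if np.isscalar(ref_count) and np.isscalar(alt_count):
        return float(score)
    return score


def score_records(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach the ``ase_score`` column to an allele-count table."""
    out = counts.copy()
    out["ase_score"] = compute_ase_score(
        out["ref_count"].to_numpy(), out["alt_count"].to_numpy()
    )
    return out


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores plus two sentinels."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - _SENTINEL_OFFSET], mids, [u[-1] + _SENTINEL_OFFSET]))


def roc_curve_hom(scores: np.ndarray, is_hom: np.ndarray) -> pd.DataFrame:
    """ROC for "score >= threshold => call homozygous" over all candidates.

    TPR is the fraction of homozygous loci called, FPR the fraction of
    heterozygous loci miscalled, at each candidate threshold.
    """
    scores = np.asarray(scores, dtype=float)
    is_hom = np.asarray(is_hom, dtype=bool)
    hom_sorted = np.sort(scores[is_hom])
    het_sorted = np.sort(scores[~is_hom])
    cands = _candidate_thresholds(scores)
    tpr = 1.0 - np.searchsorted(hom_sorted, cands, side="left") / len(hom_sorted)
    fpr = 1.0 - np.searchsorted(het_sorted, cands, side="left") / len(het_sorted)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": cands})


def youden_j_threshold(scores: np.ndarray, is_hom: np.ndarray) -> float:
    """Candidate threshold maximizing Youden's J = TPR - FPR.

    Ties on J are broken towards the smallest candidate, which discards
    more potential artifacts.
    """
    roc = roc_curve_hom(scores, is_hom)
    j = roc["tpr"].to_numpy() - roc["fpr"].to_numpy()
    return float(roc["threshold"].to_numpy()[int(np.argmax(j))])


def _as_hom_mask(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    lab = np.char.lower(labels.astype(str))
    known = {"het", "hom", ZYGOSITY_HET, ZYGOSITY_HOM}
    unknown = set(np.unique(lab)) - known
    if unknown:
        raise ValueError(f"unknown zygosity label(s): {sorted(unknown)}")
    return np.isin(lab, ("hom", ZYGOSITY_HOM))


def calibrate_threshold(
    scores, labels, n_resamples: int = 1000, seed: int = 0
) -> ThresholdEstimate:
    """Calibrate the homozygosity score threshold on genotyped loci.

    For each resample both classes are downsampled without replacement to
    the minority class size; the Youden-optimal cut is recorded and the
    final threshold is the mean across resamples. Deterministic given
    ``seed``.

    Parameters
    ----------
    scores
        ASE scores of the calibration loci.
    labels
        Matching zygosity labels: "het"/"hom" (or long forms), or a
        boolean is-homozygous mask.
    """
    scores = np.asarray(scores, dtype=float)
    is_hom = _as_hom_mask(labels)
    if scores.shape != is_hom.shape:
        raise ValueError("scores and labels must have equal length")
    if n_resamples < 1:
        raise ValueError(f"n_resamples must be >= 1, got {n_resamples}")
    idx_hom = np.flatnonzero(is_hom)
    idx_het = np.flatnonzero(~is_hom)
    if len(idx_hom) == 0 or len(idx_het) == 0:
        raise CalibrationError(
            f"both classes required: {len(idx_het)} het, {len(idx_hom)} hom"
        )
    m = min(len(idx_hom), len(idx_het))
    rng = np.random.default_rng(seed)
    thresholds = np.empty(n_resamples)
    for i in range(n_resamples):
        take = np.concatenate(
            [rng.choice(idx_het, size=m, replace=False),
             rng.choice(idx_hom, size=m, replace=False)]
        )
        thresholds[i] = youden_j_threshold(scores[take], is_hom[take])
    estimate = ThresholdEstimate(
        threshold=float(thresholds.mean()),
        per_resample_thresholds=thresholds,
        n_resamples=n_resamples,
        n_het=len(idx_het),
        n_hom=len(idx_hom),
        roc_points=roc_curve_hom(scores, is_hom),
    )
    logger.info(
        "calibrated threshold %.4f from %d het / %d hom loci (%d resamples)",
        estimate.threshold, estimate.n_het, estimate.n_hom, n_resamples,
    )
    return estimate


def classify_and_filter(
    scored: pd.DataFrame,
    genotypes: pd.DataFrame | None,
    threshold: float | None,
) -> pd.DataFrame:
    """Call zygosity per locus and flag which records survive filtering.

    Samples present in ``genotypes`` are classified from their genotype
    calls (authoritative; matched on sample_id, contig, position): only
    heterozygous loci are retained and count records without a genotype
    call are dropped. All other samples are classified by the score
    threshold: ``ase_score >= threshold`` is called homozygous and
    dropped.

    Returns the full scored table with added ``zygosity_source``
    ("genotype" or "threshold") and ``retained`` columns; use
    :func:`filter_retained` to subset. Filtering decisions are logged.
    """
    df = scored.copy()
    has_geno = genotypes is not None and len(genotypes) > 0
    geno_samples: set[str] = set(genotypes["sample_id"]) if has_geno else set()
    by_threshold = ~df["sample_id"].isin(geno_samples)
    if threshold is None:
        if by_threshold.any():
            raise ValueError(
                "a threshold is required: not every sample has genotype calls"
            )
        threshold = 1.0  # unused; keeps the arithmetic below well-defined
    elif not 0.5 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0.5, 1), got {threshold}")

    if has_geno:
        merged = df.merge(
            genotypes[["sample_id", "contig", "position", "zygosity"]],
            on=["sample_id", "contig", "position"],
            how="left",
        )
        zygosity = merged["zygosity"]
    else:
        zygosity = pd.Series(pd.NA, index=df.index)

    df["zygosity_source"] = np.where(by_threshold, "threshold", "genotype")
    retained = np.where(
        by_threshold,
        df["ase_score"].to_numpy() < threshold,
        zygosity.eq(ZYGOSITY_HET).to_numpy(),
    )
    df["retained"] = retained

    n_geno = int((~by_threshold).sum())
    n_unmatched = int(((~by_threshold) & zygosity.isna().to_numpy()).sum())
    n_hom_geno = int(((~by_threshold) & zygosity.eq(ZYGOSITY_HOM).to_numpy()).sum())
    n_thresh = int(by_threshold.sum())
    n_hom_thresh = int((by_threshold & ~retained).sum())
    logger.info(
        "classify_and_filter: %d genotype-classified records "
        "(%d homozygous dropped, %d without genotype call dropped); "
        "%d threshold-classified records (%d at/above %.4f dropped)",
        n_geno, n_hom_geno, n_unmatched, n_thresh, n_hom_thresh, threshold,
    )
    df.attrs["n_unmatched_genotyped"] = n_unmatched
    return df


def filter_retained(classified: pd.DataFrame) -> pd.DataFrame:
    """Subset a classified table to the retained (heterozygous) records."""
    return classified.loc[classified["retained"]].reset_index(drop=True)
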
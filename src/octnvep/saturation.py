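"""Saturation predictions over all possible missense variants, plus
population carrier-frequency estimates.

Every residue of an L-residue protein admits 19 substitutions, so the full
saturation table has 19*L rows.  The classifier's LOF probability p is mapped
to a normalized functional score s in [0, 1] whose 0.5 point sits exactly at
the model's decision cutoff: s > 0.5 predicts function above the LOF
threshold, with scores near 1 (near 0) indicating confident functional
(confident LOF) predictions.

Carrier frequency for an autosomal recessive condition is estimated from the
pooled allele frequency q of LOF variants in a population as the
Hardy-Weinberg heterozygote frequency 2q(1-q), reported as "1:N".  Variants
lacking an allele frequency in a population contribute 0, so the estimate is
a minimum.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import CANONICAL_AA
from .core import MissenseVariant, ProteinSequence, TopologyMap
from .features import FeatureSources, FeatureMatrix, extract_features
from .model import PenalizedModel

POPULATIONS = ("African", "EastAsian", "European", "Latino", "SouthAsian")


def enumerate_missense(seq: ProteinSequence) -> list[MissenseVariant]:
    """All 19*L possible substitutions, ordered by (position, alt)."""
    out = []
    for pos in range(1, len(seq) + 1):
        ref = seq[pos]
        for alt in CANONICAL_AA:  # alphabetical
            if alt != ref:
                out.append(MissenseVariant(pos=pos, ref=ref, alt=alt))
    return out


def normalize_score(p: float | np.ndarray, cutoff: float) -> float | np.ndarray:
    """Map LOF probability to the normalized functional score.

    Piecewise linear with the decision cutoff pinned to 0.5:
    p = 0 -> s = 1, p = cutoff -> s = 0.5, p = 1 -> s = 0.  Strictly
    decreasing and a bijection of [0, 1] for any cutoff in (0, 1), so
    classifying by s > 0.5 is identical to classifying by p < cutoff.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    s = np.where(
        p_arr <= cutoff,
        0.5 + 0.5 * (cutoff - p_arr) / cutoff,
        0.5 - 0.5 * (p_arr - cutoff) / (1.0 - cutoff),
    )
    return float(s) if np.isscalar(p) or np.ndim(p) == 0 else s


def predict_saturation(
    model: PenalizedModel,
    fm: FeatureMatrix,
    sources: FeatureSources,
    *,
    feature_set: str = "sequence",
    batch: int = 4000,
) -> pd.DataFrame:
    """Score every possible missense variant with a trained classifier.

    Features are extracted with the same sources the model was trained on and
    transformed with the model's stored scaling.  Returns the saturation
    table: variant, pos, ref, alt, p_lof, functional_score, predicted_class.
    """
    if model.cutoff is None:
        raise ValueError("classifier has no cutoff; train/select one first")
    variants = enumerate_missense(sources.seq)
    frames = []
    for i in range(0, len(variants), batch):
        chunk = variants[i : i + batch]
        raw = extract_features(chunk, sources, feature_set)
        Xs = fm.transform(raw)
        p = model.predict_proba(Xs)
        frames.append(
            pd.DataFrame(
                {
                    "variant": [v.label for v in chunk],
                    "pos": [v.pos for v in chunk],
                    "ref": [v.ref for v in chunk],
                    "alt": [v.alt for v in chunk],
                    "p_lof": p,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["functional_score"] = normalize_score(table["p_lof"].to_numpy(), model.cutoff)
    table["predicted_class"] = np.where(
        table["functional_score"] > 0.5, "functional", "lof"
    )
    return table


def saturation_summary(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-residue mean +/- SD of the functional score and global LOF counts.

    The table must be complete: exactly 19 substitutions per position.
    """
    counts = table.groupby("pos").size()
    if (counts != 19).any():
        bad = counts[counts != 19].index.tolist()
        raise ValueError(f"incomplete saturation table at position(s) {bad[:5]}")
    per_res = (
        table.groupby("pos")["functional_score"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    n_lof = int((table["functional_score"] < 0.5).sum())
    global_counts = {
        "n_variants": int(len(table)),
        "n_predicted_lof": n_lof,
        "frac_predicted_lof": n_lof / len(table),
    }
    return per_res, global_counts


def heatmap_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Positions x alternate-residue matrix of functional scores.

    Substitution rows follow the fixed alphabetical one-letter ordering;
    reference cells (alt == ref) are NaN ("missing"), matching the convention
    of leaving reference residues blank in saturation heatmaps.
    """
    m = table.pivot(index="alt", columns="pos", values="functional_score")
    return m.reindex(index=list(CANONICAL_AA))


# ---------------------------------------------------------------------------
# Carrier frequencies

def read_population_af_tsv(path: str | Path) -> pd.DataFrame:
    """Read per-population allele frequencies (variant, population, allele_frequency)."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant", "population", "allele_frequency"}
    if not required.issubset(df.columns):
        raise ValueError(f"population AF TSV needs columns {sorted(required)}")
    af = df["allele_frequency"].astype(float)
    if ((af < 0) | (af >= 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1)")
    return df


def carrier_frequency(
    lof_variants: Iterable[str],
    afs: pd.DataFrame,
    population: str,
    *,
    formula: str = "hardy-weinberg",
) -> tuple[float, float, str | None]:
    """Minimum carrier frequency for a population.

    q is the sum of the population allele frequencies of the LOF variants
    (absent entries contribute 0); the carrier frequency is the heterozygote
    frequency 2q(1-q) (``formula="2q"`` selects the simpler approximation).
    Returns (q, carrier_frequency, "1:N" or None when q == 0).
    """
    lof = set(lof_variants)
    sub = afs[(afs["population"] == population) & (afs["variant"].isin(lof))]
    q = float(sub["allele_frequency"].sum())
    if q >= 1:
        raise ValueError(f"pooled allele frequency q={q} >= 1")
    if formula == "hardy-weinberg":
        cf = 2.0 * q * (1.0 - q)
    elif formula == "2q":
        cf = 2.0 * q
    else:
        raise ValueError(f"unknown formula {formula!r}")
    ratio = f"1:{round(1.0 / cf)}" if cf > 0 else None
    return q, cf, ratio


def carrier_frequency_table(
    lof_variants: Iterable[str],
    afs: pd.DataFrame,
    populations: Sequence[str] = POPULATIONS,
    *,
    formula: str = "hardy-weinberg",
) -> pd.DataFrame:
    lof = list(lof_variants)
    rows = []
    for pop in populations:
        q, cf, ratio = carrier_frequency(lof, afs, pop, formula=formula)
        rows.append(
            {"population": pop, "q": q, "carrier_frequency": cf, "ratio": ratio}
        )
    return pd.DataFrame(rows).set_index("population")
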
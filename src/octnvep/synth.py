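"""Synthetic characterization studies with known ground truth.

The generator emulates the statistical structure of a transporter variant
characterization study end to end: a 12-transmembrane protein with 25
topological regions; a panel of missense variants drawn over the sequence;
a sparse linear-logistic ground truth mapping scaled sequence features to a
latent liability; true mean function on a 120 * logistic(-liability) scale
(so values span a realistic range with tails slightly below 0 and above
100 %WT); raw uptake replicates obtained by inverting the %WT normalization
and adding Gaussian replicate noise; three-class localization generated from
ordered thresholds on true function plus label noise; eight ancestry-style
groups with a small "Clinical" group enriched for LOF; and rare (< 0.01)
per-population allele frequencies.

Everything is reproducible: identical (config, seed) gives an identical
study, byte for byte when serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import assay as assay_mod
from .chemistry import CANONICAL_AA, KYTE_DOOLITTLE
from .core import MissenseVariant, ProteinSequence, Region, TopologyMap, write_topology_tsv
from .features import FeatureMatrix, FeatureSources, StructureModel, extract_features

GROUPS = (
    "Shared",
    "Random",
    "African",
    "EastAsian",
    "European",
    "Latino",
    "SouthAsian",
    "Clinical",
)

#: Region layout: intracellular N-terminus, 12 TMs with alternating
#: extracellular/intracellular loops (EL1 is the large glycosylated loop,
#: EL2 and EL5 are only a few residues), intracellular C-terminus.
_REGION_ORDER: tuple[tuple[str, str], ...] = (
    ("N-term", "N-term"),
    ("TM1", "TM"), ("EL1", "EL"), ("TM2", "TM"), ("IL1", "IL"),
    ("TM3", "TM"), ("EL2", "EL"), ("TM4", "TM"), ("IL2", "IL"),
    ("TM5", "TM"), ("EL3", "EL"), ("TM6", "TM"), ("IL3", "IL"),
    ("TM7", "TM"), ("EL4", "EL"), ("TM8", "TM"), ("IL4", "IL"),
    ("TM9", "TM"), ("EL5", "EL"), ("TM10", "TM"), ("IL5", "IL"),
    ("TM11", "TM"), ("EL6", "EL"), ("TM12", "TM"), ("C-term", "C-term"),
)

_REGION_WEIGHTS: dict[str, int] = {
    "N-term": 45, "C-term": 54, "EL1": 90, "EL2": 4, "EL3": 12,
    "EL4": 10, "EL5": 3, "EL6": 12,
    **{f"IL{i}": 15 for i in range(1, 6)},
    **{f"TM{i}": 21 for i in range(1, 13)},
}


def synthetic_topology(L: int = 557) -> TopologyMap:
    """A 25-region topology (1 N-term, 12 TM, 6 EL, 5 IL, 1 C-term) tiling 1..L.

    Region lengths are scaled from a canonical 557-residue layout by largest
    remainder, each region keeping at least one residue (requires L >= 25).
    """
    names = [n for n, _ in _REGION_ORDER]
    if L < len(names):
        raise ValueError(f"need L >= {len(names)} to fit 25 regions, got {L}")
    w = np.array([_REGION_WEIGHTS[n] for n in names], dtype=float)
    ideal = w / w.sum() * L
    lengths = np.maximum(np.floor(ideal).astype(int), 1)
    # distribute the remainder by largest fractional part, deterministically
    while lengths.sum() < L:
        frac = ideal - lengths
        lengths[int(np.argmax(frac))] += 1
    while lengths.sum() > L:
        order = np.argsort(ideal - lengths)
        for i in order:
            if lengths[i] > 1:
                lengths[i] -= 1
                break
    regions, start = [], 1
    for (name, cls), ln in zip(_REGION_ORDER, lengths):
        regions.append(Region(name=name, cls=cls, start=start, end=start + int(ln) - 1))
        start += int(ln)
    return TopologyMap(regions)


_HYDROPHOBIC = "AILMFVWC"


def synthetic_sequence(
    topo: TopologyMap, seed: int = 0, seq_id: str = "SYNTHETIC"
) -> ProteinSequence:
    """Random sequence over the topology: TM regions biased hydrophobic,
    loops biased hydrophilic — realistic enough for hydropathy features to
    co-vary with topology as in a real transporter."""
    rng = np.random.default_rng(seed)
    aas = np.array(list(CANONICAL_AA))
    kd = np.array([KYTE_DOOLITTLE[a] for a in aas])
    w_tm = np.exp(0.6 * kd)
    w_loop = np.exp(-0.25 * kd)
    residues = []
    for r in topo.regions:
        w = w_tm if r.cls == "TM" else w_loop
        p = w / w.sum()
        residues.extend(rng.choice(aas, size=len(r), p=p))
    return ProteinSequence(id=seq_id, residues="".join(residues))


def synthetic_helix(
    n_res: int, seed: int = 0, *, confidence_range: tuple[float, float] = (50.0, 95.0)
) -> StructureModel:
    """Ideal alpha-helix C-alpha trace with random per-residue confidence.

    2.3 A helix radius, 1.5 A rise and 100 degrees twist per residue — a
    minimal coordinate model sufficient for contact/burial features.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_res) * np.deg2rad(100.0)
    coords = np.column_stack(
        (2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_res))
    )
    lo, hi = confidence_range
    return StructureModel(coords=coords, confidence=rng.uniform(lo, hi, n_res))


# ---------------------------------------------------------------------------
# Configuration and truth

#: Sparse ground-truth coefficients on 0-1 scaled sequence features.
#: Positive pushes toward LOF: transmembrane location is damaging while
#: conservative substitutions (high BLOSUM62) and hydropathy-preserving
#: changes are protective.  The three predictors are individually
#: identifiable at n=150 (common, not collinear), so parameter-recovery
#: checks against this truth are well posed.
DEFAULT_BETA: dict[str, float] = {
    "class_TM": 2.0,
    "blosum62": -3.0,
    "delta_hydropathy": -1.5,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs; defaults mirror a 150-variant characterization of a
    557-residue transporter with ~25% LOF prevalence."""

    L: int = 557
    n_variants: int = 150
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    target_lof_prevalence: float = 0.25
    lof_threshold: float = 20.0
    function_scale: float = 120.0  # %WT at liability -> -inf
    n_bio: int = 3
    n_tech: int = 3
    bio_noise_sd: float = 8.0  # %WT, between biological replicates
    tech_noise_sd: float = 4.0  # %WT-equivalent, between technical wells
    wt_counts: float = 1000.0  # counts/ug for wild type
    ev_counts: float = 50.0  # counts/ug empty-vector background
    batch_size: int = 30  # variants per assay batch
    loc_thresholds: tuple[float, float] = (30.0, 65.0)  # %WT: intracellular/mixed/membrane
    loc_noise: float = 0.15  # label-noise rate for localization
    clinical_size: int = 10
    clinical_lof_weight: float = 8.0  # enrichment weight for LOF in Clinical
    af_scale: float = 5e-4
    af_max: float = 0.01
    n_score_tables: int = 2  # synthetic external-predictor score columns
    score_noise_sd: float = 1.0  # on the liability scale
    score_missing_rate: float = 0.05

    @classmethod
    def smoke(cls, **kw) -> "SyntheticConfig":
        """Small fast profile for tests."""
        return cls(L=60, n_variants=40, batch_size=20, **kw)


@dataclass
class SyntheticTruth:
    """The generating parameters, for recovery assertions."""

    beta: dict[str, float]
    intercept: float
    liability: pd.Series  # per variant
    true_function: pd.Series  # per variant, %WT
    bio_noise_sd: float
    loc_noise: float
    seed: int


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    seed: int
    seq: ProteinSequence
    topo: TopologyMap
    variants: list[MissenseVariant]
    sources: FeatureSources
    X_raw: pd.DataFrame  # raw (unscaled) feature table, all feature sets
    raw_assay: pd.DataFrame
    characterized: pd.DataFrame  # pipeline output + localization/group/AF columns
    af_table: pd.DataFrame
    truth: SyntheticTruth


def truth_report(study: SyntheticStudy) -> SyntheticTruth:
    """The study's generating parameters (for parameter-recovery checks)."""
    return study.truth


def _draw_variants(
    rng: np.random.Generator, seq: ProteinSequence, n: int
) -> list[MissenseVariant]:
    seen: set[str] = set()
    out: list[MissenseVariant] = []
    while len(out) < n:
        pos = int(rng.integers(1, len(seq) + 1))
        ref = seq[pos]
        alt = str(rng.choice([a for a in CANONICAL_AA if a != ref]))
        v = MissenseVariant(pos=pos, ref=ref, alt=alt)
        if v.label not in seen:
            seen.add(v.label)
            out.append(v)
    return out


def _truncated_exponential(rng: np.random.Generator, scale: float, cap: float) -> float:
    while True:
        x = float(rng.exponential(scale))
        if x < cap:
            return x


def simulate_study(
    config: SyntheticConfig | None = None, seed: int = 0
) -> SyntheticStudy:
    """Generate a complete synthetic characterization study.

    See the module docstring for the generative model.  The liability
    intercept is set so that the design fraction of variants falls below the
    LOF threshold in true (noiseless) function, matching the study's target
    LOF prevalence.
    """
    cfg = config or SyntheticConfig()
    if not 0 < cfg.target_lof_prevalence < 1:
        raise ValueError("target LOF prevalence must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)

    topo = synthetic_topology(cfg.L)
    seq = synthetic_sequence(topo, seed=int(rng.integers(2**31 - 1)))
    # canonical label order so features, truth and the characterized table align
    variants = sorted(_draw_variants(rng, seq, cfg.n_variants), key=lambda v: v.label)
    labels = [v.label for v in variants]

    # --- ground-truth liability from scaled sequence features
    seq_sources = FeatureSources(seq=seq, topo=topo)
    seq_raw = extract_features(variants, seq_sources, "sequence")
    missing_beta = [k for k in cfg.beta if k not in seq_raw.columns]
    if missing_beta:
        raise ValueError(f"beta names not among sequence features: {missing_beta}")
    scaled = FeatureMatrix(seq_raw).fit_scaling().transform()
    eta = pd.Series(0.0, index=scaled.index)
    for k, b in cfg.beta.items():
        eta = eta + scaled[k] * b
    # function < threshold  <=>  liability > logit(1 - threshold/scale)
    lof_liability = float(np.log(cfg.function_scale / cfg.lof_threshold - 1.0))
    intercept = lof_liability - float(
        np.quantile(eta, 1.0 - cfg.target_lof_prevalence)
    )
    liability = intercept + eta
    true_function = cfg.function_scale * expit(-liability.to_numpy())
    true_function = pd.Series(true_function, index=labels, name="true_function")

    # --- raw uptake replicates (affine inverse of the %WT normalization)
    span = cfg.wt_counts - cfg.ev_counts
    tech_sd_counts = cfg.tech_noise_sd / 100.0 * span
    batches = {
        labels[i]: f"batch{i // cfg.batch_size + 1:02d}" for i in range(len(labels))
    }
    raw_rows = []

    def emit(construct: str, batch: str, f_mean: float) -> None:
        for b in range(1, cfg.n_bio + 1):
            f_b = f_mean + rng.normal(0.0, cfg.bio_noise_sd)
            mu_counts = cfg.ev_counts + f_b / 100.0 * span
            for t in range(1, cfg.n_tech + 1):
                raw_rows.append(
                    {
                        "variant": construct,
                        "batch": batch,
                        "bio_rep": b,
                        "tech_rep": t,
                        "uptake_counts_per_ug": mu_counts
                        + rng.normal(0.0, tech_sd_counts),
                    }
                )

    for batch in sorted(set(batches.values())):
        emit(assay_mod.WT_LABEL, batch, 100.0)
        emit(assay_mod.EV_LABEL, batch, 0.0)
    for lab in labels:
        emit(lab, batches[lab], float(true_function[lab]))
    raw_assay = pd.DataFrame(raw_rows)

    # --- localization from ordered thresholds on true function + label noise
    t_lo, t_hi = cfg.loc_thresholds
    loc = np.where(
        true_function < t_lo,
        "intracellular",
        np.where(true_function < t_hi, "mixed", "membrane"),
    ).astype(object)
    for i in range(len(loc)):
        if rng.random() < cfg.loc_noise:
            others = [c for c in assay_mod.LOCALIZATION_CLASSES if c != loc[i]]
            loc[i] = str(rng.choice(others))
    localization = pd.Series(loc, index=labels, name="localization")

    # --- groups: Clinical enriched for LOF, others uniform
    lof_true = (true_function < cfg.lof_threshold).to_numpy()
    weights = np.where(lof_true, cfg.clinical_lof_weight, 1.0).astype(float)
    weights /= weights.sum()
    n_clin = min(cfg.clinical_size, len(labels) - len(GROUPS) + 1)
    clin_idx = rng.choice(len(labels), size=n_clin, replace=False, p=weights)
    group = pd.Series("", index=labels, name="group", dtype=object)
    group.iloc[clin_idx] = "Clinical"
    rest = [l for l in labels if group[l] == ""]
    other_groups = [g for g in GROUPS if g != "Clinical"]
    assignments = [other_groups[i % len(other_groups)] for i in range(len(rest))]
    rng.shuffle(assignments)
    group.loc[rest] = assignments

    # --- rare allele frequencies per population
    presence_by_group = {
        "African": {"African": 1.0},
        "EastAsian": {"EastAsian": 1.0},
        "European": {"European": 1.0},
        "Latino": {"Latino": 1.0},
        "SouthAsian": {"SouthAsian": 1.0},
        "Shared": {p: 0.6 for p in ("African", "EastAsian", "European", "Latino", "SouthAsian")},
        "Random": {p: 0.3 for p in ("African", "EastAsian", "European", "Latino", "SouthAsian")},
        "Clinical": {p: 0.3 for p in ("African", "EastAsian", "European", "Latino", "SouthAsian")},
    }
    af_rows = []
    for lab in labels:
        for pop, prob in presence_by_group[group[lab]].items():
            if rng.random() < prob:
                af_rows.append(
                    {
                        "variant": lab,
                        "population": pop,
                        "allele_frequency": _truncated_exponential(
                            rng, cfg.af_scale, cfg.af_max
                        ),
                    }
                )
    af_table = pd.DataFrame(af_rows, columns=["variant", "population", "allele_frequency"])

    # --- synthetic external-predictor score tables (liability + noise)
    score_tables: dict[str, dict[str, float]] = {}
    for k in range(cfg.n_score_tables):
        name = f"synthpred{k + 1}"
        table = {}
        for lab in labels:
            if rng.random() < cfg.score_missing_rate:
                continue
            table[lab] = float(
                liability[lab] + rng.normal(0.0, cfg.score_noise_sd)
            )
        score_tables[name] = table

    sources = FeatureSources(
        seq=seq, topo=topo, structure=None, score_tables=score_tables
    )
    X_raw = extract_features(variants, sources, "all")

    # --- run the assay pipeline on the raw replicates
    characterized = assay_mod.characterize(
        raw_assay, lof_threshold=cfg.lof_threshold
    )
    characterized["localization"] = localization
    characterized["group"] = group
    wide_af = af_table.pivot(index="variant", columns="population", values="allele_frequency")
    for pop in ("African", "EastAsian", "European", "Latino", "SouthAsian"):
        col = wide_af[pop] if pop in wide_af.columns else np.nan
        characterized[f"af_{pop}"] = col
    characterized["true_function"] = true_function

    truth = SyntheticTruth(
        beta=dict(cfg.beta),
        intercept=intercept,
        liability=pd.Series(liability.to_numpy(), index=labels, name="liability"),
        true_function=true_function,
        bio_noise_sd=cfg.bio_noise_sd,
        loc_noise=cfg.loc_noise,
        seed=seed,
    )
    return SyntheticStudy(
        config=cfg,
        seed=seed,
        seq=seq,
        topo=topo,
        variants=variants,
        sources=sources,
        X_raw=X_raw,
        raw_assay=raw_assay,
        characterized=characterized,
        af_table=af_table,
        truth=truth,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a study to the same plain-text formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = out / "sequence.fasta"
    seq_lines = [f">{study.seq.id}"]
    seq_lines += [study.seq.residues[i : i + 60] for i in range(0, len(study.seq), 60)]
    fasta.write_text("\n".join(seq_lines) + "\n")
    paths["fasta"] = fasta

    topo = out / "topology.tsv"
    write_topology_tsv(study.topo, topo)
    paths["topology"] = topo

    raw = out / "raw_assay.tsv"
    study.raw_assay.to_csv(raw, sep="\t", index=False, float_format="%.6f")
    paths["raw_assay"] = raw

    char = out / "characterized.tsv"
    study.characterized.to_csv(char, sep="\t", float_format="%.6f")
    paths["characterized"] = char

    af = out / "population_af.tsv"
    study.af_table.to_csv(af, sep="\t", index=False, float_format="%.8f")
    paths["population_af"] = af

    for name, table in study.sources.score_tables.items():
        p = out / f"scores_{name}.tsv"
        pd.DataFrame(
            {"variant": list(table), "score": list(table.values())}
        ).to_csv(p, sep="\t", index=False, float_format="%.6f")
        paths[f"scores_{name}"] = p
    return paths
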
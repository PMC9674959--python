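"""Feature extraction for missense variants of a membrane transporter.

Three feature families are provided, mirroring the information sources a
transporter-specific effect predictor can draw on:

* ``sequence`` — properties of the amino-acid change and its position in the
  membrane topology (region class, hydropathy / charge / volume deltas,
  substitution-matrix score, proline/glycine flags);
* ``structure`` — per-residue descriptors from a 3-D model (model confidence,
  contact number, relative burial, distance from the central pore axis);
* ``prediction`` — pass-through scores from external variant effect
  predictors, joined by variant label.

:class:`FeatureMatrix` carries the assembled variants x features table
together with fitted min-max scaling (and mean-imputation) parameters so that
held-out variants are transformed exactly as the training set was.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import chemistry
from .core import (
    REGION_CLASSES,
    MissenseVariant,
    ProteinSequence,
    TopologyMap,
)

FEATURE_SETS = ("sequence", "structure", "prediction", "all")


# ---------------------------------------------------------------------------
# Structure model

@dataclass
class StructureModel:
    """Per-residue C-alpha coordinates and model confidence.

    ``coords`` has one row per sequence position (1..L); rows of NaN mark
    residues without coordinates.  ``confidence`` is the per-residue model
    confidence on a 0-100 scale (pLDDT for AlphaFold-style models, read from
    the B-factor field).
    """

    coords: np.ndarray  # (L, 3) C-alpha coordinates, NaN where missing
    confidence: np.ndarray  # (L,)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.coords.shape != (len(self.confidence), 3):
            raise ValueError("coords must be (L, 3) matching confidence length")

    @property
    def length(self) -> int:
        return len(self.confidence)

    def has_coords(self, pos: int) -> bool:
        return bool(np.isfinite(self.coords[pos - 1]).all())


def read_structure(path: str | Path, chain: str | None = None) -> StructureModel:
    """Read C-alpha coordinates and per-residue B-factor from PDB/mmCIF.

    For AlphaFold-style files the B-factor column carries pLDDT.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = [c for c in model if chain is None or c.name == chain]
    if not chains:
        raise ValueError(f"chain {chain!r} not found in {path}")
    ch = chains[0]
    coords, conf = [], []
    for res in ch:
        ca = res.find_atom("CA", "*")
        if ca is None:
            coords.append((np.nan, np.nan, np.nan))
            conf.append(np.nan)
        else:
            coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
            conf.append(ca.b_iso)
    return StructureModel(coords=np.array(coords), confidence=np.array(conf))


def contact_numbers(coords: np.ndarray, radius: float = 10.0) -> np.ndarray:
    """Number of C-alpha neighbours within ``radius`` Angstroms of each residue.

    The residue itself is excluded; residues without coordinates get NaN and
    never count as neighbours.
    """
    from scipy.spatial.distance import cdist

    coords = np.asarray(coords, dtype=float)
    ok = np.isfinite(coords).all(axis=1)
    out = np.full(len(coords), np.nan)
    if ok.sum() == 0:
        return out
    sub = coords[ok]
    d = cdist(sub, sub)
    counts = ((d <= radius).sum(axis=1) - 1).astype(float)  # subtract self
    out[ok] = counts
    return out


def pore_axis_distances(coords: np.ndarray) -> np.ndarray:
    """Distance of each residue from the protein's central (principal) axis.

    The axis passes through the coordinate centroid along the first principal
    component — for an elongated membrane transporter this approximates the
    membrane normal through the translocation pore, so small distances mark
    pore-lining residues.
    """
    coords = np.asarray(coords, dtype=float)
    ok = np.isfinite(coords).all(axis=1)
    out = np.full(len(coords), np.nan)
    if ok.sum() < 2:
        return out
    sub = coords[ok]
    centroid = sub.mean(axis=0)
    centered = sub - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    perp = centered - np.outer(proj, axis)
    out[ok] = np.linalg.norm(perp, axis=1)
    return out


# ---------------------------------------------------------------------------
# Extractors

def sequence_features(
    v: MissenseVariant,
    seq: ProteinSequence,
    topo: TopologyMap,
    *,
    hydropathy: Mapping[str, float] = chemistry.KYTE_DOOLITTLE,
    charge: Mapping[str, int] = chemistry.SIDE_CHAIN_CHARGE,
    volume: Mapping[str, float] = chemistry.RESIDUE_VOLUME,
) -> dict[str, float]:
    """Sequence- and topology-based features for one substitution.

    Depends only on (pos, ref, alt, topology) — never on assay outcomes.
    """
    region = topo.region_of(v.pos)
    feats: dict[str, float] = {"position": float(v.pos)}
    for cls in REGION_CLASSES:
        feats[f"class_{cls}"] = 1.0 if region.cls == cls else 0.0
    for r in topo.regions:
        feats[f"region_{r.name}"] = 1.0 if r.name == region.name else 0.0
    feats["delta_hydropathy"] = hydropathy[v.alt] - hydropathy[v.ref]
    feats["delta_charge"] = float(charge[v.alt] - charge[v.ref])
    feats["delta_volume"] = volume[v.alt] - volume[v.ref]
    feats["blosum62"] = chemistry.blosum62_score(v.ref, v.alt)
    feats["proline_introduced"] = 1.0 if v.alt == "P" else 0.0
    feats["glycine_removed"] = 1.0 if v.ref == "G" else 0.0
    return feats


def structure_features(
    v: MissenseVariant,
    model: StructureModel,
    *,
    contact_radius: float = 10.0,
    _cache: dict | None = None,
) -> dict[str, float]:
    """Structure-based features for the residue a substitution touches.

    Residues without coordinates yield NaN values, to be imputed downstream.
    """
    if _cache is not None and "cn" in _cache:
        cn, axd = _cache["cn"], _cache["axd"]
    else:
        cn = contact_numbers(model.coords, radius=contact_radius)
        axd = pore_axis_distances(model.coords)
        if _cache is not None:
            _cache.update(cn=cn, axd=axd)
    i = v.pos - 1
    max_cn = np.nanmax(cn) if np.isfinite(cn).any() else np.nan
    c = cn[i]
    rel = c / max_cn if np.isfinite(c) and max_cn and max_cn > 0 else (0.0 if c == 0 else np.nan)
    return {
        "plddt": float(model.confidence[i]),
        "contact_number": float(c),
        "relative_burial": float(rel),
        "pore_axis_distance": float(axd[i]),
    }


def prediction_features(
    v: MissenseVariant,
    score_tables: Mapping[str, Mapping[str, float]],
) -> dict[str, float]:
    """Join external predictor scores by variant label.

    Absent scores are NaN here; :func:`assemble` mean-imputes them on the
    training rows and adds a ``<name>_missing`` indicator column.
    """
    feats: dict[str, float] = {}
    for name, table in score_tables.items():
        s = table.get(v.label, np.nan)
        feats[f"score_{name}"] = float(s)
        feats[f"score_{name}_missing"] = 0.0 if np.isfinite(float(s)) else 1.0
    return feats


def read_score_table(path: str | Path) -> dict[str, float]:
    """Read a TSV of external predictor scores (columns: variant, score)."""
    df = pd.read_csv(path, sep="\t")
    if not {"variant", "score"}.issubset(df.columns):
        raise ValueError(f"score table {path} needs columns variant, score")
    if df["variant"].duplicated().any():
        dupes = df.loc[df["variant"].duplicated(), "variant"].tolist()
        raise ValueError(f"duplicate variant keys in {path}: {dupes}")
    return dict(zip(df["variant"], df["score"].astype(float)))


# ---------------------------------------------------------------------------
# Registry and assembled matrix

@dataclass
class FeatureSources:
    """Everything the extractors may need, bundled."""

    seq: ProteinSequence
    topo: TopologyMap
    structure: StructureModel | None = None
    score_tables: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


def extract_features(
    variants: Sequence[MissenseVariant],
    sources: FeatureSources,
    feature_set: str = "all",
    *,
    contact_radius: float = 10.0,
) -> pd.DataFrame:
    """Raw (unscaled) feature table for ``variants``, indexed by label."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    want_seq = feature_set in ("sequence", "all")
    want_struct = feature_set in ("structure", "all") and sources.structure is not None
    if feature_set == "structure" and sources.structure is None:
        raise ValueError("structure feature set requested but no structure model given")
    want_pred = feature_set in ("prediction", "all") and bool(sources.score_tables)
    if feature_set == "prediction" and not sources.score_tables:
        raise ValueError("prediction feature set requested but no score tables given")

    cache: dict = {}
    rows = {}
    for v in variants:
        feats: dict[str, float] = {}
        if want_seq:
            feats.update(sequence_features(v, sources.seq, sources.topo))
        if want_struct:
            feats.update(
                structure_features(
                    v, sources.structure, contact_radius=contact_radius, _cache=cache
                )
            )
        if want_pred:
            feats.update(prediction_features(v, sources.score_tables))
        rows[v.label] = feats
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "variant"
    return df


class FeatureMatrix:
    """Variants x features table with stored 0-1 scaling parameters.

    ``fit=True`` learns per-column (min, max) — and mean-imputation values for
    columns with missing entries — from the given rows; subsequent
    :meth:`transform` calls apply those parameters and clip new values into
    [0, 1].  Constant columns scale to 0 everywhere (an L1 penalty removes
    them anyway) and are listed in :attr:`constant_columns`.
    """

    def __init__(self, raw: pd.DataFrame):
        self.raw = raw.copy()
        self.mins: pd.Series | None = None
        self.maxs: pd.Series | None = None
        self.impute_means: pd.Series | None = None
        self.constant_columns: list[str] = []

    @property
    def columns(self) -> list[str]:
        return list(self.raw.columns)

    def fit_scaling(self) -> "FeatureMatrix":
        filled = self.raw.copy()
        means = filled.mean(axis=0, skipna=True).fillna(0.0)
        filled = filled.fillna(means)
        self.impute_means = means
        self.mins = filled.min(axis=0)
        self.maxs = filled.max(axis=0)
        self.constant_columns = [
            c for c in filled.columns if self.maxs[c] == self.mins[c]
        ]
        return self

    def transform(self, rows: pd.DataFrame | None = None) -> pd.DataFrame:
        if self.mins is None:
            raise RuntimeError("scaling not fitted; call fit_scaling() first")
        df = self.raw if rows is None else rows
        if list(df.columns) != list(self.raw.columns):
            df = df.reindex(columns=self.raw.columns)
        vals = df.to_numpy(dtype=float, copy=True)
        means = self.impute_means.to_numpy(dtype=float)
        nan_mask = np.isnan(vals)
        if nan_mask.any():
            vals[nan_mask] = np.broadcast_to(means, vals.shape)[nan_mask]
        mins = self.mins.to_numpy(dtype=float)
        span = self.maxs.to_numpy(dtype=float) - mins
        const = span == 0
        span = np.where(const, 1.0, span)
        scaled = (vals - mins) / span
        scaled[:, const] = 0.0  # constant columns -> 0
        np.clip(scaled, 0.0, 1.0, out=scaled)
        return pd.DataFrame(scaled, index=df.index, columns=df.columns)

    def inverse_transform(self, scaled: pd.DataFrame) -> pd.DataFrame:
        if self.mins is None:
            raise RuntimeError("scaling not fitted")
        return scaled * (self.maxs - self.mins) + self.mins

    def scaling_params(self) -> dict:
        if self.mins is None:
            raise RuntimeError("scaling not fitted")
        return {
            "min": self.mins.to_dict(),
            "max": self.maxs.to_dict(),
            "impute_mean": self.impute_means.to_dict(),
        }

    def to_tsv(self, path: str | Path, sidecar_json: str | Path | None = None) -> None:
        self.raw.to_csv(path, sep="\t")
        if sidecar_json is not None:
            import json

            Path(sidecar_json).write_text(json.dumps(self.scaling_params(), indent=1))


def assemble(
    variants: Sequence[MissenseVariant],
    sources: FeatureSources,
    feature_set: str = "all",
    *,
    fit: bool = True,
    contact_radius: float = 10.0,
) -> FeatureMatrix:
    """Extract the requested feature set and (optionally) fit 0-1 scaling."""
    fm = FeatureMatrix(
        extract_features(variants, sources, feature_set, contact_radius=contact_radius)
    )
    if fit:
        fm.fit_scaling()
    return fm
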
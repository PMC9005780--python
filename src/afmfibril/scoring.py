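"""Similarity scoring and ranking of cryo-EM candidates against an
AFM-imaged fibril.

The image score is the correlation distance d_img = 1 - r, with the
Pearson correlation r computed over the experimental pixels above the
estimated fibril-axis height.  Morphometric parameters (helical symmetry
sym, handedness hnd, cross-over distance cod, cross-sectional area csa
and cross-sectional difference area csd) contribute absolute differences
normalised to the maximum observed across the candidate panel (fixed
norm 2 for hnd), and the combined score d_sum is the plain sum of the
six components; lower means more similar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import NormalisationWarning, UndefinedScoreError
from .sections import CrossSection
from .tipsim import HeightMap

COMPONENTS = ("d_img", "d_sym", "d_hnd", "d_cod", "d_csa", "d_csd")


@dataclass
class MorphometricSet:
    """Morphometric parameters of one fibril (or candidate map)."""

    sym: int
    hnd: int
    cod_nm: float
    csa_nm2: float
    csd_nm2: Optional[float] = None  # pairwise, vs. the reference

    def __post_init__(self) -> None:
        if self.sym < 1:
            raise ValueError("sym must be >= 1")
        if self.hnd not in (-1, 1):
            raise ValueError("hnd must be -1 or +1")
        if self.cod_nm <= 0 or self.csa_nm2 <= 0:
            raise ValueError("cod and csa must be positive")
        if self.csd_nm2 is not None and self.csd_nm2 < 0:
            raise ValueError("csd must be >= 0")


@dataclass
class ReferenceFibril:
    """Everything measured from the experimental AFM fibril."""

    image: HeightMap  # straightened topograph
    axis_height_nm: float
    morph: MorphometricSet
    cross_section: CrossSection


@dataclass
class CandidateMeasurements:
    """Fully processed candidate: aligned simulated image + morphometrics."""

    label: str
    sim_image: HeightMap  # periodicity-optimised, on the reference grid
    morph: MorphometricSet
    provenance: Dict = field(default_factory=dict)


@dataclass
class SimilarityReport:
    """Per-candidate component scores, combined score and rank."""

    table: pd.DataFrame
    excluded: Dict[str, str] = field(default_factory=dict)
    provenance: Dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_json(self, path) -> None:
        payload = {
            "candidates": self.table.to_dict(orient="records"),
            "excluded": self.excluded,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["label"])


def image_distance(data: HeightMap, sim: HeightMap, axis_height_nm: float) -> float:
    """Correlation distance d_img = 1 - r over the above-axis mask.

    Only experimental pixels strictly above the estimated fibril-axis
    height enter the Pearson correlation, which avoids the strongly
    tip-convolved flanks near the substrate.
    """
    if data.heights.shape != sim.heights.shape:
        raise ValueError("data and sim images must share a shape")
    mask = data.heights > axis_height_nm
    if mask.sum() < 3:
        raise UndefinedScoreError("above-axis mask is (nearly) empty")
    x = data.heights[mask]
    y = sim.heights[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedScoreError("zero variance under the mask")
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def param_distance(value_candidate: float, value_reference: float, norm_max: float) -> float:
    """Normalised parameter distance |par_c - par_ref| / norm_max in [0, 1].

    ``norm_max`` is the maximum absolute difference observed across the
    candidate panel (fixed at the theoretical maximum 2 for handedness).
    If every candidate matches the reference (norm_max == 0) the
    distance is defined as 0, with a warning.
    """
    if norm_max < 0:
        raise ValueError("norm_max must be >= 0")
    if norm_max == 0:
        warnings.warn(
            "all candidates identical for this parameter; distance set to 0",
            NormalisationWarning,
        )
        return 0.0
    return abs(value_candidate - value_reference) / norm_max


def combined_score(components: Dict[str, float]) -> float:
    """Combined similarity score: the plain sum of the six components."""
    missing = [k for k in COMPONENTS if k not in components]
    if missing:
        raise ValueError(f"missing score components: {missing}")
    vals = [float(components[k]) for k in COMPONENTS]
    if any(v < 0 for v in vals):
        raise ValueError("score components must be >= 0")
    return float(sum(vals))


def rank_candidates(
    reference: ReferenceFibril,
    candidates: List[CandidateMeasurements],
    excluded: Optional[Dict[str, str]] = None,
) -> SimilarityReport:
    """Score and rank processed candidates against the reference fibril.

    Component distances use the panel-wide maximum observed difference
    as normalisation (Eq.-style standardisation), so scores are relative
    to the candidate set; ranks sort ascending by d_sum with ties broken
    by d_img and then label.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to rank")
    ref = reference.morph

    def deltas(par):
        return [abs(par(c.morph)) for c in candidates]

    norm = {
        "d_sym": max(deltas(lambda m: m.sym - ref.sym)),
        "d_hnd": 2.0,
        "d_cod": max(deltas(lambda m: m.cod_nm - ref.cod_nm)),
        "d_csa": max(deltas(lambda m: m.csa_nm2 - ref.csa_nm2)),
        "d_csd": max(abs(c.morph.csd_nm2 or 0.0) for c in candidates),
    }
    rows = []
    for c in candidates:
        if c.morph.csd_nm2 is None:
            raise ValueError(f"candidate {c.label} lacks csd vs reference")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NormalisationWarning)
            comp = {
                "d_img": image_distance(
                    reference.image, c.sim_image, reference.axis_height_nm
                ),
                "d_sym": param_distance(c.morph.sym, ref.sym, norm["d_sym"]),
                "d_hnd": param_distance(c.morph.hnd, ref.hnd, norm["d_hnd"]),
                "d_cod": param_distance(c.morph.cod_nm, ref.cod_nm, norm["d_cod"]),
                "d_csa": param_distance(c.morph.csa_nm2, ref.csa_nm2, norm["d_csa"]),
                "d_csd": param_distance(c.morph.csd_nm2, 0.0, norm["d_csd"]),
            }
        rows.append({"label": c.label, **comp, "d_sum": combined_score(comp)})
    table = pd.DataFrame(rows).sort_values(
        by=["d_sum", "d_img", "label"], kind="stable", ignore_index=True
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return SimilarityReport(
        table=table,
        excluded=dict(excluded or {}),
        provenance={c.label: c.provenance for c in candidates},
    )
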
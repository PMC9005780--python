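"""End-to-end workflows tying the stages together.

Candidate side: density map -> iso-surface -> denoise -> long-axis
alignment -> screw-axis fit -> helical extension -> simulated topograph
on the reference grid -> periodicity optimisation; morphometrics from
the untwisted, tip-accessible cross-section plus the helical metadata.

Reference side: straightened AFM topograph -> cross-over distance ->
symmetry detection -> 3D envelope -> cross-section and axis height.

Ranking combines both through :func:`afmfibril.scoring.rank_candidates`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import afm_image, envelope, helical, map_io, morphometrics, scoring, tipsim
from .errors import AfmFibrilError
from .map_io import HelicalParams, SurfaceCloud, VolumeGrid
from .sections import CrossSection
from .tipsim import HeightMap, TipModel

log = logging.getLogger(__name__)


@dataclass
class CandidateEntry:
    """One cryo-EM candidate: a map (or surface) plus helical metadata."""

    label: str
    helical: HelicalParams
    volume: Optional[VolumeGrid] = None
    surface: Optional[SurfaceCloud] = None
    isovalue: Optional[float] = None
    provenance: Optional[Dict] = None


@dataclass
class ProcessedCandidate:
    """Axis-fitted candidate surface with its tip-accessible section."""

    label: str
    surface: SurfaceCloud  # screw axis on z
    helical: HelicalParams
    cross_section: CrossSection
    csa_nm2: float
    pose: Optional[helical.ScrewAxisPose] = None
    provenance: Optional[Dict] = None


def process_candidate(
    entry: CandidateEntry,
    tip: TipModel,
    denoise: bool = True,
    axis_fit_mode: str = "joint",
) -> ProcessedCandidate:
    """Run the map-side pipeline for one candidate entry."""
    if entry.surface is not None:
        surf = entry.surface
    elif entry.volume is not None:
        surf = map_io.extract_isosurface(entry.volume, entry.isovalue)
        if denoise:
            surf = map_io.denoise_surface(surf)
    else:
        raise ValueError(f"candidate {entry.label} has neither volume nor surface")
    surf, _ = map_io.align_long_axis(surf)
    surf, pose = helical.fit_screw_axis(surf, entry.helical, mode=axis_fit_mode)
    pts2d = helical.untwist_to_plane(surf, entry.helical)
    cs = morphometrics.tip_accessible_boundary(pts2d, tip.radius_nm)
    csa = morphometrics.cross_section_area(cs)
    return ProcessedCandidate(
        label=entry.label,
        surface=surf,
        helical=entry.helical,
        cross_section=cs,
        csa_nm2=csa,
        pose=pose,
        provenance=dict(entry.provenance or {}, overlap=pose.overlap_score),
    )


@dataclass
class ReferenceBundle:
    """Processed experimental fibril: image, envelope and morphometrics."""

    image: HeightMap
    tip: TipModel
    envelope: envelope.Envelope3D
    cross_section: CrossSection
    morph: scoring.MorphometricSet
    axis_height_nm: float
    axis_x_nm: float


def process_reference(
    straight_img: HeightMap,
    tip: TipModel,
    handedness: int = -1,
    symmetry_candidates: Sequence[int] = (1, 2),
    cod_nm: Optional[float] = None,
) -> ReferenceBundle:
    """Measure an AFM fibril: cross-over, symmetry, envelope, section.

    The envelope cross-section is passed through the tip-accessible
    boundary with the same tip radius used for the candidate maps, which
    keeps AFM- and cryo-EM-derived sections comparable.
    """
    ny = straight_img.shape[0]
    profile = straight_img.heights[:, straight_img.shape[1] // 2]
    if cod_nm is None:
        cod_nm, _ = afm_image.crossover_distance(profile, straight_img.pixel_size_nm)
    n, _, _ = envelope.detect_symmetry(
        straight_img, tip, cod_nm, candidates=symmetry_candidates, handedness=handedness
    )
    env = envelope.reconstruct_envelope(straight_img, tip, n, cod_nm, handedness)
    cs_raw = envelope.envelope_cross_section(env)
    try:
        cs = morphometrics.tip_accessible_boundary(cs_raw.points, tip.radius_nm)
    except AfmFibrilError:
        # thin near-circular curves can defeat the alpha shape (co-circular
        # triangles); the envelope section is already a contact surface
        cs = cs_raw
    cs = CrossSection(points=cs.points, axis_xy=cs_raw.axis_xy)
    csa = morphometrics.cross_section_area(cs)
    eroded = tipsim.erode_topograph(
        envelope._denoise_for_deconvolution(straight_img), tip
    )
    axis_x, _ = envelope._estimate_axis(
        eroded.heights, straight_img.pixel_size_nm, straight_img.x0
    )
    morph = scoring.MorphometricSet(sym=n, hnd=handedness, cod_nm=cod_nm, csa_nm2=csa)
    return ReferenceBundle(
        image=straight_img,
        tip=tip,
        envelope=env,
        cross_section=cs,
        morph=morph,
        axis_height_nm=env.axis_height_nm,
        axis_x_nm=axis_x,
    )


def simulate_candidate_image(
    proc: ProcessedCandidate,
    reference: ReferenceBundle,
) -> Tuple[float, HeightMap, float]:
    """Simulate a candidate topograph on the reference grid and optimise
    its periodicity against the experimental image.

    The candidate surface is helically extended to twice the reference
    image length (so contraction/dilation never runs out of rows), laid
    on the substrate with its axis along y at the reference's estimated
    axis position, and imaged with the reference tip.
    """
    data = reference.image
    px = data.pixel_size_nm
    length = (data.shape[0] - 1) * px
    surf = helical.extend_helical(proc.surface, proc.helical, 2.0 * length)
    img_frame = tipsim.to_image_frame(surf)
    v = img_frame.vertices
    v = v + np.array([reference.axis_x_nm, data.y0 - v[:, 1].min(), 0.0])
    ny_sim = 2 * data.shape[0]
    sim = tipsim.simulate_topograph(
        img_frame.replace(vertices=v),
        reference.tip,
        px,
        grid_shape=(ny_sim, data.shape[1]),
        grid_origin=(data.x0, data.y0),
        densify=False,
    )
    # the twist pattern repeats every cross-over, so one period of axial
    # registration shift suffices
    max_shift = int(np.ceil(reference.morph.cod_nm / px)) + 2
    return tipsim.optimize_periodicity(sim, data, max_shift_rows=max_shift)


def rank_panel(
    reference: ReferenceBundle,
    entries: Sequence[CandidateEntry],
    processed: Optional[Dict[str, ProcessedCandidate]] = None,
) -> scoring.SimilarityReport:
    """Full comparison of one AFM fibril against a candidate map panel.

    Candidates whose pipeline fails are excluded from the ranking with
    the failure reason recorded in the report (never silently dropped).
    ``processed`` allows reuse of candidate-side work across repeats.
    """
    if len(entries) < 2:
        raise ValueError("need at least 2 candidate entries")
    measured: List[scoring.CandidateMeasurements] = []
    excluded: Dict[str, str] = {}
    for entry in entries:
        try:
            proc = (processed or {}).get(entry.label) or process_candidate(
                entry, reference.tip
            )
            scale, sim, ncc = simulate_candidate_image(proc, reference)
            csd = morphometrics.cross_section_difference(
                proc.cross_section, reference.cross_section
            )
            morph = scoring.MorphometricSet(
                sym=proc.helical.symmetry_order,
                hnd=proc.helical.handedness,
                cod_nm=proc.helical.crossover_nm,
                csa_nm2=proc.csa_nm2,
                csd_nm2=csd,
            )
            measured.append(
                scoring.CandidateMeasurements(
                    label=entry.label,
                    sim_image=sim,
                    morph=morph,
                    provenance=dict(
                        proc.provenance or {}, periodicity_scale=scale, ncc=ncc
                    ),
                )
            )
        except AfmFibrilError as exc:
            log.warning("candidate %s excluded: %s", entry.label, exc)
            excluded[entry.label] = f"{type(exc).__name__}: {exc}"
    ref = scoring.ReferenceFibril(
        image=reference.image,
        axis_height_nm=reference.axis_height_nm,
        morph=reference.morph,
        cross_section=reference.cross_section,
    )
    report = scoring.rank_candidates(ref, measured, excluded=excluded)
    return report


def validate_map_reconstruction(
    volume: VolumeGrid,
    helical_params: HelicalParams,
    tip_radius_nm: float = 11.7,
    pixel_nm: float = 3000.0 / 2048,
    image_length_nm: Optional[float] = None,
    denoise: bool = True,
) -> Dict[str, float]:
    """Round-trip validation of the 3D reconstruction on a known map.

    Simulates a topograph from the extended, axis-aligned iso-surface,
    reconstructs the envelope from that topograph alone, and reports the
    RMSD between the reconstruction's cross-section and the
    tip-accessible cross-section of the input map, plus the fitted
    screw-axis offset from the section centre of mass.
    """
    tip = TipModel(radius_nm=tip_radius_nm)
    entry = CandidateEntry(label="input", helical=helical_params, volume=volume,
                           isovalue=volume.isovalue)
    proc = process_candidate(entry, tip, denoise=denoise)
    cod = helical_params.crossover_nm
    if image_length_nm is None:
        image_length_nm = max(2.5 * cod, 3 * cod)
    surf = helical.extend_helical(proc.surface, helical_params, image_length_nm)
    img = tipsim.simulate_topograph(tipsim.to_image_frame(surf), tip, pixel_nm)
    env = envelope.reconstruct_envelope(
        img, tip, helical_params.symmetry_order, cod, helical_params.handedness
    )
    cs_rec = envelope.envelope_cross_section(env)
    _, rmsd = morphometrics.align_cross_sections(proc.cross_section, cs_rec)
    com_offset = float(np.linalg.norm(proc.cross_section.centroid - proc.cross_section.axis_xy))
    return {
        "cross_section_rmsd_nm": rmsd,
        "axis_offset_from_com_nm": com_offset,
        "symmetry_order": helical_params.symmetry_order,
        "axis_overlap_score": proc.pose.overlap_score,
        "axis_height_nm": env.axis_height_nm,
    }
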
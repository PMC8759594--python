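"""Synthetic fluorescence scenes and tables with known ground truth.

Every input the analysis consumes can be generated here with a recorded
ground truth, so the whole pipeline is testable without microscope data:

* FISH scenes: nuclei containing foci whose sub-puncta number and spread
  control the dispersion read-out;
* cytoplasmic puncta scenes with a size mixture straddling the 1 um
  countability boundary;
* DAPI/PLA/EdU multichannel scenes with border-touching (and optionally
  fused) nuclei;
* qPCR crossing-point (Cp) tables with a designated origin locus;
* transcripts x alleles expression matrices with transcripts planted to
  correlate with a dispersion ranking.

Foci and puncta are rendered as sums of isotropic Gaussians / filled discs on
a uniform background with additive Gaussian noise, clipped to [0, 1]; there
is no point-spread-function or camera-noise realism, and no 3D rendering
(the analysis operates on max projections).  All randomness flows from one
explicit seed through `numpy.random.SeedSequence` spawns, one stream per
scene element, so each fixture is individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quant import CpTable

__all__ = [
    "SyntheticSceneParams",
    "SyntheticScene",
    "SceneGenerationError",
    "generate_fish_scene",
    "generate_puncta_scene",
    "generate_pla_scene",
    "generate_expression_matrix",
    "generate_cp_table",
]


class SceneGenerationError(RuntimeError):
    """Raised when object placement cannot satisfy the requested constraints."""


@dataclass(frozen=True)
class SyntheticSceneParams:
    """Parameters of a synthetic FISH scene.

    Defaults approximate a 63x/1.4 NA confocal field of RPE1-like nuclei:
    0.1 um/px calibration, ~4 um nuclear semi-axes, sub-puncta of 0.15 um
    radius.  ``focus_spread_um`` is the standard deviation of sub-puncta
    placement around the focus centre and is the dispersion knob:
    ``focus_spread_um = 0`` produces a single compact blob per focus.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    n_nuclei: int = 2
    foci_per_nucleus: int = 2
    subpuncta_per_focus: int = 32
    focus_spread_um: float = 0.5
    subpunctum_radius_um: float = 0.2
    noise_sd: float = 0.005
    background_level: float = 0.05
    nucleus_radius_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subpuncta_per_focus < 1:
            raise ValueError("subpuncta_per_focus must be >= 1")
        if self.focus_spread_um < 0:
            raise ValueError("focus_spread_um must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.subpunctum_radius_um > 0:
            raise ValueError("subpunctum_radius_um must be positive")
        if not 0 <= self.background_level < 1:
            raise ValueError("background_level must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticScene:
    """A rendered scene plus its ground-truth record and companion channels."""

    image: np.ndarray
    truth: dict
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    params: object | None = None
    pixel_size_um: float = 0.1


def _add_gaussian(image: np.ndarray, r: float, c: float, sigma_px: float, amplitude: float) -> None:
    """Accumulate an isotropic Gaussian spot into ``image`` in place."""
    h, w = image.shape
    half = max(2, int(math.ceil(4 * sigma_px)))
    r0, r1 = max(0, int(r) - half), min(h, int(r) + half + 1)
    c0, c1 = max(0, int(c) - half), min(w, int(c) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma_px**2)
    )


def _add_disc(image: np.ndarray, r: float, c: float, radius_px: float, amplitude: float) -> None:
    h, w = image.shape
    half = int(math.ceil(radius_px)) + 1
    r0, r1 = max(0, int(r) - half), min(h, int(r) + half + 1)
    c0, c1 = max(0, int(c) - half), min(w, int(c) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - r) ** 2 + (cc - c) ** 2 <= radius_px**2
    image[r0:r1, c0:c1][inside] = np.maximum(image[r0:r1, c0:c1][inside], amplitude)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], angle: float) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    radius_px: float,
    min_separation_px: float,
    margin_px: float,
    max_tries: int = 5000,
    what: str = "nuclei",
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping centres, failing loudly."""
    h, w = shape
    lo_r, hi_r = margin_px, h - margin_px
    lo_c, hi_c = margin_px, w - margin_px
    if lo_r >= hi_r or lo_c >= hi_c:
        raise SceneGenerationError(
            f"image {shape} too small to place {n} {what} of radius "
            f"{radius_px:.1f} px with margin {margin_px:.1f} px"
        )
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries:
            raise SceneGenerationError(
                f"could not place {n} non-overlapping {what} (radius "
                f"{radius_px:.1f} px, separation {min_separation_px:.1f} px) in "
                f"image {shape} after {max_tries} attempts"
            )
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if all((r - r2) ** 2 + (c - c2) ** 2 >= min_separation_px**2 for r2, c2 in centers):
            centers.append((r, c))
    return centers


def _finalize(image: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    image = np.clip(image, 0.0, 1.0)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return np.clip(image, 0.0, 1.0)


def generate_fish_scene(params: SyntheticSceneParams) -> SyntheticScene:
    """Render a FISH field of nuclei with dispersed multi-punctum foci.

    Each focus is a cluster of ``subpuncta_per_focus`` Gaussian sub-puncta
    scattered around the focus centre with standard deviation
    ``focus_spread_um``; the emitted truth record carries nucleus and focus
    identities, focus centres and every sub-punctum coordinate.  Companion
    channels: a DAPI rendering of the nuclei and a binary nucleolus mask
    (one disc per nucleus).
    """
    p = params
    ss = np.random.SeedSequence(p.seed)
    rng_place, rng_foci, rng_noise, rng_shape = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    h, w = p.image_size_px
    px = p.pixel_size_um
    nucleus_r_px = p.nucleus_radius_um / px
    centers = _place_centers(
        rng_place, p.n_nuclei, (h, w), nucleus_r_px,
        min_separation_px=2.2 * nucleus_r_px, margin_px=nucleus_r_px * 1.05,
    )

    fish = np.full((h, w), p.background_level)
    dapi = np.full((h, w), 0.02)
    nucleolus = np.zeros((h, w), dtype=bool)
    nuclei_truth, foci_truth = [], []
    sigma_px = p.subpunctum_radius_um / px
    spread_px = p.focus_spread_um / px
    focus_id = 0
    for nid, (cr, cc) in enumerate(centers):
        ecc = rng_shape.uniform(0.0, 0.6)
        a = nucleus_r_px
        b = a * math.sqrt(1 - ecc**2)
        angle = rng_shape.uniform(0, math.pi)
        mask = _ellipse_mask((h, w), (cr, cc), (a, b), angle)
        dapi[mask] = np.maximum(dapi[mask], 0.45)
        nuclei_truth.append(
            {"nucleus_id": nid, "center_px": (cr, cc), "axes_px": (a, b),
             "angle": angle, "eccentricity": ecc}
        )
        # one nucleolus disc per nucleus, kept away from the nuclear rim
        nuc_r = min(1.5 / px, 0.3 * b)
        nr = cr + rng_shape.uniform(-0.3, 0.3) * b
        nc = cc + rng_shape.uniform(-0.3, 0.3) * b
        rr, ccg = np.mgrid[0:h, 0:w]
        nucleolus |= (rr - nr) ** 2 + (ccg - nc) ** 2 <= nuc_r**2

        # foci centres well inside the nucleus so sub-puncta stay within it;
        # placement restarts from scratch when a partial layout dead-ends
        inner = 0.55
        n_foci = p.foci_per_nucleus
        sep = max(12.0, spread_px + 6.0 * sigma_px)
        placed: list[tuple[float, float]] = []
        for _attempt in range(500):
            placed = []
            for _ in range(200 * n_foci):
                t = rng_foci.uniform(0, 2 * math.pi)
                rad = math.sqrt(rng_foci.uniform(0, 1.0)) * inner
                u, v = rad * math.cos(t) * a, rad * math.sin(t) * b
                fr = cr + u * math.cos(angle) - v * math.sin(angle)
                fc = cc + u * math.sin(angle) + v * math.cos(angle)
                if all((fr - r2) ** 2 + (fc - c2) ** 2 >= sep**2 for r2, c2 in placed):
                    placed.append((fr, fc))
                    if len(placed) == n_foci:
                        break
            if len(placed) == n_foci:
                break
        else:
            raise SceneGenerationError(
                f"could not place {n_foci} foci {sep:.0f} px apart inside "
                f"nucleus {nid}; reduce foci_per_nucleus or focus_spread_um"
            )
        for fr, fc in placed:
            if p.subpuncta_per_focus == 1 or spread_px == 0:
                offsets = np.zeros((p.subpuncta_per_focus, 2))
            else:
                offsets = rng_foci.normal(0.0, spread_px, size=(p.subpuncta_per_focus, 2))
            subs = np.array([fr, fc]) + offsets
            for sr, sc in subs:
                _add_gaussian(fish, sr, sc, sigma_px, amplitude=0.9)
            foci_truth.append(
                {"focus_id": focus_id, "nucleus_id": nid, "center_px": (fr, fc),
                 "spread_um": p.focus_spread_um,
                 "subpuncta_px": [tuple(map(float, s)) for s in subs]}
            )
            focus_id += 1

    fish = _finalize(fish, rng_noise, p.noise_sd)
    dapi = _finalize(dapi, rng_noise, p.noise_sd)
    return SyntheticScene(
        image=fish,
        truth={"nuclei": nuclei_truth, "foci": foci_truth},
        channels={"dapi": dapi, "nucleolus_mask": nucleolus},
        params=p,
        pixel_size_um=px,
    )


def generate_puncta_scene(
    n_large: int,
    n_small: int,
    large_diameter_um: float = 1.5,
    small_diameter_um: float = 0.6,
    seed: int = 0,
    image_size_px: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.1,
    noise_sd: float = 0.01,
) -> SyntheticScene:
    """A single-cell crop with a size mixture of bright puncta.

    Large puncta (diameter >= 1 um) are the countable autophagosome-like
    objects; small ones (< 1 um) are the sub-micrometre background speckles
    removed by the counting rule.  The truth labels each punctum with its
    diameter and countability.
    """
    if large_diameter_um < 1.0:
        raise ValueError("large_diameter_um must be >= 1 um")
    if small_diameter_um >= 1.0:
        raise ValueError("small_diameter_um must be < 1 um")
    ss = np.random.SeedSequence(seed)
    rng_place, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    h, w = image_size_px
    px = pixel_size_um
    r_large = large_diameter_um / 2 / px
    r_small = small_diameter_um / 2 / px
    n = n_large + n_small
    sep = 2 * r_large + max(4.0, 2 * r_large)
    centers = _place_centers(
        rng_place, n, (h, w), r_large, min_separation_px=sep,
        margin_px=r_large + 3, what="puncta",
    )
    image = np.full((h, w), 0.05)
    truth = []
    for i, (r, c) in enumerate(centers):
        is_large = i < n_large
        radius = r_large if is_large else r_small
        diameter = large_diameter_um if is_large else small_diameter_um
        _add_disc(image, r, c, radius, amplitude=0.9)
        truth.append(
            {"punctum_id": i, "center_px": (r, c), "diameter_um": diameter,
             "countable": bool(diameter >= 1.0)}
        )
    image = _finalize(image, rng_noise, noise_sd)
    return SyntheticScene(
        image=image, truth={"puncta": truth}, params=None, pixel_size_um=px
    )


def generate_pla_scene(
    n_nuclei: int = 5,
    n_border_nuclei: int = 0,
    foci_per_nucleus: int = 4,
    edu_positive_fraction: float = 0.5,
    seed: int = 0,
    image_size_px: tuple[int, int] = (384, 384),
    pixel_size_um: float = 0.2,
    nucleus_radius_um: float = 5.5,
    n_fused_pairs: int = 0,
    dapi_noise_sd: float = 0.05,
    noise_sd: float = 0.005,
) -> SyntheticScene:
    """A DAPI/PLA/EdU field for the nucleus segmentation pipeline.

    ``n_border_nuclei`` of the ``n_nuclei`` total intersect the frame border
    by construction; fused pairs (two overlapping ellipses forming one
    low-circularity object) can be added to exercise the merged-nuclei
    filter.  Per-nucleus truth: interior/border status, PLA focus count, EdU
    class and DNA content (2N for G1, 4N for G2, intermediate for S), with
    DAPI intensity proportional to DNA content up to ``dapi_noise_sd``
    multiplicative noise.
    """
    if n_border_nuclei > n_nuclei:
        raise ValueError("n_border_nuclei cannot exceed n_nuclei")
    if not 0 <= edu_positive_fraction <= 1:
        raise ValueError("edu_positive_fraction must be in [0, 1]")
    ss = np.random.SeedSequence(seed)
    rng_place, rng_shape, rng_foci, rng_cycle, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    h, w = image_size_px
    px = pixel_size_um
    r_px = nucleus_radius_um / px
    n_interior = n_nuclei - n_border_nuclei

    interior = _place_centers(
        rng_place, n_interior + n_fused_pairs, (h, w), r_px,
        min_separation_px=2.6 * r_px, margin_px=1.3 * r_px,
    )
    fused_seeds = interior[n_interior:]
    interior = interior[:n_interior]

    # border nuclei: centres ON the frame edge so the component must touch it
    border: list[tuple[float, float]] = []
    edges = [(0.0, None), (float(h - 1), None), (None, 0.0), (None, float(w - 1))]
    tries = 0
    while len(border) < n_border_nuclei:
        tries += 1
        if tries > 5000:
            raise SceneGenerationError("could not place border nuclei")
        er, ec = edges[rng_place.integers(0, 4)]
        r = er if er is not None else rng_place.uniform(1.3 * r_px, h - 1.3 * r_px)
        c = ec if ec is not None else rng_place.uniform(1.3 * r_px, w - 1.3 * r_px)
        if all(
            (r - r2) ** 2 + (c - c2) ** 2 >= (2.6 * r_px) ** 2
            for r2, c2 in interior + border + fused_seeds
        ):
            border.append((r, c))

    n_edu_pos = int(round(edu_positive_fraction * n_nuclei))
    edu_pos_ids = set(rng_cycle.choice(n_nuclei, size=n_edu_pos, replace=False).tolist())
    # EdU-negative nuclei carry a balanced, shuffled 2N/4N (G1/G2) mixture so
    # both DAPI modes are always planted
    neg_ids = [i for i in range(n_nuclei) if i not in edu_pos_ids]
    neg_classes = [("G1", 2.0) if i % 2 == 0 else ("G2", 4.0) for i in range(len(neg_ids))]
    rng_cycle.shuffle(neg_classes)
    neg_class_by_id = dict(zip(neg_ids, neg_classes))

    dapi = np.full((h, w), 0.02)
    pla = np.full((h, w), 0.02)
    edu = np.full((h, w), 0.02)
    nuclei_truth = []
    all_centers = [(rc, False) for rc in interior] + [(rc, True) for rc in border]
    for nid, ((cr, cc), is_border) in enumerate(all_centers):
        ecc = rng_shape.uniform(0.0, 0.5)
        a = r_px
        b = a * math.sqrt(1 - ecc**2)
        angle = rng_shape.uniform(0, math.pi)
        mask = _ellipse_mask((h, w), (cr, cc), (a, b), angle)
        edu_positive = nid in edu_pos_ids
        if edu_positive:
            cycle, dna = "S", float(rng_cycle.uniform(2.2, 3.8))
        else:
            cycle, dna = neg_class_by_id[nid]
        level = 0.18 * dna * (1 + rng_noise.normal(0, dapi_noise_sd)) / 2.0
        dapi[mask] = np.maximum(dapi[mask], level)
        if edu_positive:
            edu[mask] = np.maximum(edu[mask], 0.8)
        # PLA foci strictly inside the nucleus and the frame, separated so
        # individual foci remain resolvable after thresholding
        n_foci = foci_per_nucleus
        spot_sigma = 0.3 / px
        placed_foci: list[tuple[float, float]] = []
        tries = 0
        while len(placed_foci) < n_foci:
            tries += 1
            if tries > 20000:
                raise SceneGenerationError(f"could not place PLA foci in nucleus {nid}")
            t = rng_foci.uniform(0, 2 * math.pi)
            rad = math.sqrt(rng_foci.uniform(0, 1.0)) * 0.7
            u, v = rad * math.cos(t) * a, rad * math.sin(t) * b
            fr = cr + u * math.cos(angle) - v * math.sin(angle)
            fc = cc + u * math.sin(angle) + v * math.cos(angle)
            if not (2 <= fr < h - 2 and 2 <= fc < w - 2):
                continue
            min_sep = 6.0 * spot_sigma
            if any((fr - r2) ** 2 + (fc - c2) ** 2 < min_sep**2 for r2, c2 in placed_foci):
                continue
            _add_gaussian(pla, fr, fc, spot_sigma, amplitude=0.9)
            placed_foci.append((fr, fc))
        nuclei_truth.append(
            {"nucleus_id": nid, "center_px": (cr, cc), "border": bool(is_border),
             "pla_foci_count": n_foci, "edu_positive": bool(edu_positive),
             "cycle_class": cycle, "dna_content": dna, "fused": False}
        )

    for fid, (cr, cc) in enumerate(fused_seeds):
        # two overlapping ellipses -> one elongated low-circularity component
        off = 0.8 * r_px
        for s in (-1.0, 1.0):
            mask = _ellipse_mask((h, w), (cr, cc + s * off), (0.55 * r_px, 0.9 * r_px), 0.0)
            dapi[mask] = np.maximum(dapi[mask], 0.18)
        nuclei_truth.append(
            {"nucleus_id": n_nuclei + fid, "center_px": (cr, cc), "border": False,
             "pla_foci_count": 0, "edu_positive": False, "cycle_class": "G1",
             "dna_content": 2.0, "fused": True}
        )

    dapi = _finalize(dapi, rng_noise, noise_sd)
    pla = _finalize(pla, rng_noise, noise_sd)
    edu = _finalize(edu, rng_noise, noise_sd)
    return SyntheticScene(
        image=dapi,
        truth={"nuclei": nuclei_truth},
        channels={"dapi": dapi, "pla": pla, "edu": edu},
        params=None,
        pixel_size_um=px,
    )


def generate_expression_matrix(
    ranking,
    n_planted_pos: int,
    n_planted_neg: int,
    n_noise: int,
    target_abs_r: float = 0.9,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Transcripts x alleles expression matrix with planted correlations.

    ``ranking`` is a dispersion ranking object (anything with a
    ``covariate()`` method returning an allele-indexed Series), a Series, or
    an array of per-allele covariate values.  Planted transcripts are linear
    transforms of the standardized covariate plus Gaussian noise calibrated
    so the expected Pearson r is ``+-target_abs_r`` when ``noise_sd = 1``
    (``noise_sd = 0`` gives r = +-1 exactly); noise transcripts are
    permutation-decorrelated copies of the covariate plus noise.  Returns
    (matrix, truth labels in {planted_pos, planted_neg, noise}).
    """
    if not 0 < target_abs_r <= 1:
        raise ValueError("target_abs_r must be in (0, 1]")
    if hasattr(ranking, "covariate"):
        cov = np.asarray(ranking.covariate(), dtype=float)
        alleles = list(ranking.covariate().index)
    elif isinstance(ranking, pd.Series):
        cov = ranking.to_numpy(dtype=float)
        alleles = list(ranking.index)
    else:
        cov = np.asarray(ranking, dtype=float)
        alleles = [f"allele{i + 1}" for i in range(cov.size)]
    n_alleles = cov.size
    if n_alleles < 3:
        raise ValueError("ranking must cover >= 3 alleles (correlation undefined below)")
    z = (cov - cov.mean()) / cov.std()

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma = 0.0 if target_abs_r == 1 else math.sqrt(1.0 / target_abs_r**2 - 1.0)
    rows, labels, names = [], [], []
    for i in range(n_planted_pos):
        rows.append(z + noise_sd * sigma * rng.normal(size=n_alleles))
        labels.append("planted_pos")
        names.append(f"pos_{i + 1}")
    for i in range(n_planted_neg):
        rows.append(-z + noise_sd * sigma * rng.normal(size=n_alleles))
        labels.append("planted_neg")
        names.append(f"neg_{i + 1}")
    for i in range(n_noise):
        rows.append(rng.permutation(z) + noise_sd * rng.normal(size=n_alleles))
        labels.append("noise")
        names.append(f"noise_{i + 1}")
    # shift/scale to an RPM-like positive range; Pearson r is unaffected
    matrix = pd.DataFrame(50.0 + 10.0 * np.asarray(rows), index=names, columns=alleles)
    return matrix, pd.Series(labels, index=names, name="truth")


def generate_cp_table(
    loci: Sequence[str],
    origin_locus: str,
    deltas: Mapping[str, float],
    replicate_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    sample: str = "sample1",
    base_cp: float = 20.0,
) -> CpTable:
    """qPCR crossing-point table for 3C quantification fixtures.

    Per replicate, Cp(locus) = base + deltas[locus] + iid Gaussian noise of
    SD ``replicate_sd`` (the origin's delta is 0), so downstream
    fold-changes recover 2**deltas when the noise is zero.
    """
    loci = list(loci)
    if origin_locus not in loci:
        raise ValueError(f"origin locus {origin_locus!r} is not among loci {loci}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    for rep in range(1, n_replicates + 1):
        for locus in loci:
            delta = 0.0 if locus == origin_locus else float(deltas.get(locus, 0.0))
            cp = base_cp + delta + (rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0)
            records.append({"sample": sample, "replicate": rep, "locus": locus, "cp": cp})
    table = pd.DataFrame.from_records(records)
    return CpTable(data=table, origin_locus=origin_locus, truth_deltas=dict(deltas))
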
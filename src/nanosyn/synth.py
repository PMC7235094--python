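"""Ground-truth synaptic scene generation and forward rendering.

A scene is a list of postsynaptic densities (PSDs), each composed of one
or more elliptical ~140 nm PSD95 nanoclusters (NCs), optionally apposed
by a presynaptic bouton (VGLUT1 or VGLUT2 class, with distinct
substructure size statistics) and/or a perisynaptic astrocytic
nanodomain.  The generator records every placement and association link,
so any downstream summary (NC count per PSD, tripartite status, bouton
class) can be recomputed from truth without touching the images.

Rendering uses an analytic forward model: every object is an anisotropic
2-D Gaussian whose amplitude is its total photon count; convolution with
a Gaussian point-spread function (PSF) is therefore closed-form (the
covariances add), which gives exact oracles for photon conservation and
for the FWHM composition law ``FWHM_app² = FWHM_obj² + FWHM_psf²``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CONFOCAL_PSF_FWHM_NM,
    HIGHRES_PIXEL_NM,
    HIGHRES_PSF_FWHM_NM,
    STED_PIXEL_NM,
    STED_PSF_FWHM_NM,
    ChannelImage,
    ParameterError,
    fwhm_to_sigma,
)

__all__ = [
    "NCTruth",
    "PSDTruth",
    "BoutonTruth",
    "AstroTruth",
    "GroundTruthScene",
    "SceneParams",
    "RenderSpec",
    "generate_scene",
    "render_channel",
    "truth_summary",
    "scene_to_json",
    "scene_from_json",
]


@dataclass
class NCTruth:
    """One PSD95 nanocluster: an elliptical Gaussian emitter."""

    centre_um: tuple[float, float]
    short_axis_nm: float  # FWHM along the minor axis
    long_axis_nm: float   # FWHM along the major axis
    orientation_rad: float
    amplitude: float      # total photons

    def __post_init__(self) -> None:
        if self.short_axis_nm > self.long_axis_nm:
            raise ParameterError("short axis must not exceed long axis")


@dataclass
class PSDTruth:
    id: int
    centre_um: tuple[float, float]
    nc_list: list[NCTruth]
    lamina_label: Optional[str] = None
    linked_bouton_id: Optional[int] = None
    linked_astro_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.nc_list) < 1:
            raise ParameterError("a PSD holds at least one nanocluster")


@dataclass
class BoutonSubstructure:
    centre_um: tuple[float, float]
    diameter_nm: float  # FWHM (circular)
    amplitude: float


@dataclass
class BoutonTruth:
    id: int
    bouton_class: str  # "vglut1" | "vglut2"
    substructures: list[BoutonSubstructure]

    def __post_init__(self) -> None:
        if self.bouton_class not in ("vglut1", "vglut2"):
            raise ParameterError(f"unknown bouton class {self.bouton_class!r}")


@dataclass
class AstroTruth:
    id: int
    centre_um: tuple[float, float]
    diameter_nm: float  # FWHM (circular)
    amplitude: float
    linked_psd_id: Optional[int] = None  # None for free-floating decoys


@dataclass
class SceneParams:
    """Study conditions for scene generation.

    Densities are per µm², probabilities in [0, 1].  Defaults emulate the
    ventral-horn condition: 47% of PSDs carry 2+ nanoclusters, 45% of
    PSDs are bouton-contacted synapses, and 56% of those synapses are
    tripartite (astrocyte-contacted).  Nanocluster axis FWHMs default to
    lognormals with medians 92 nm (short) × 185 nm (long); VGLUT2 bouton
    substructures have a 90 nm median diameter versus 272 nm for VGLUT1;
    astrocytic nanodomains have a 119 nm median diameter.

    Multi-NC layout is hub-and-spoke with tangentially oriented spokes,
    a geometry chosen so the ground truth is unambiguous at both
    resolutions.  The mid-point dip of a Gaussian pair is 2·exp(−d²/8σ²)
    of the peak with σ the apparent sigma *along the separation*; since
    spokes present their short axis (σ ≈ 52 nm with the 80 nm STED PSF)
    to the hub, hub–spoke distances of 260–300 nm dip below ~0.36 of the
    peak — under the ~0.4–0.5·peak level where auto-thresholds land on
    punctate STED fields — while at confocal resolution (σ ≈ 122 nm) the
    same pair keeps its bridge above ~0.75 of the peak, so the parent
    blob stays connected.  Spokes are at least 110° apart, keeping
    spoke–spoke chords resolvable as well.
    ``contact_gap_max_nm`` is the edge–edge gap (at
    the half-maximum contour) between a PSD and its linked bouton or
    astro domain; the 0–40 nm default matches cleft-scale apposition and
    guarantees that linked partners colocalize once rendered and
    binarised.  See docs/methods.md for the derivations.
    """

    field_size_um: tuple[float, float] = (20.0, 20.0)
    psd_density_per_um2: float = 0.15
    min_psd_sep_um: float = 1.2
    edge_margin_um: float = 0.7
    nc_count_probs: dict = field(
        default_factory=lambda: {1: 0.53, 2: 0.31, 3: 0.16}
    )
    nc_disc_radius_nm: float = 300.0
    min_nc_sep_nm: float = 260.0
    nc_long_axis_median_nm: float = 185.0
    nc_long_axis_sigma_log: float = 0.20
    nc_short_axis_median_nm: float = 92.0
    nc_short_axis_sigma_log: float = 0.15
    nc_amplitude_median: float = 2.0e4
    nc_amplitude_sigma_log: float = 0.20
    synapse_fraction: float = 0.45       # P(PSD has a bouton)
    tripartite_fraction: float = 0.56    # P(astro | bouton)
    astro_only_fraction: float = 0.15    # P(astro | no bouton)
    bouton_class_mix: dict = field(default_factory=lambda: {"vglut2": 1.0})
    vglut2_diameter_median_nm: float = 90.0
    vglut1_diameter_median_nm: float = 272.0
    bouton_diameter_sigma_log: float = 0.30
    bouton_amplitude_median: float = 2.0e4
    astro_diameter_median_nm: float = 119.0
    astro_diameter_sigma_log: float = 0.20
    astro_amplitude_median: float = 1.5e4
    decoy_astro_density_per_um2: float = 0.05
    contact_gap_max_nm: float = 40.0     # edge–edge gap for linked partners
    background_rate: float = 10.0        # photons per rendered pixel

    def validate(self) -> None:
        if min(self.field_size_um) <= 0:
            raise ParameterError("field size must be positive")
        for name in ("psd_density_per_um2", "decoy_astro_density_per_um2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        for name in (
            "synapse_fraction",
            "tripartite_fraction",
            "astro_only_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")
        probs = np.array(list(self.nc_count_probs.values()), dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ParameterError("nc_count_probs must be a probability vector")
        mix = np.array(list(self.bouton_class_mix.values()), dtype=float)
        if np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
            raise ParameterError("bouton_class_mix must be a probability vector")
        if self.background_rate < 0:
            raise ParameterError("background_rate must be non-negative")


@dataclass
class GroundTruthScene:
    field_size_um: tuple[float, float]
    psds: list[PSDTruth]
    boutons: list[BoutonTruth]
    astro_domains: list[AstroTruth]
    background_rate: float
    seed: int
    params: Optional[SceneParams] = None

    def __post_init__(self) -> None:
        bouton_ids = {b.id for b in self.boutons}
        astro_ids = {a.id for a in self.astro_domains}
        w, h = self.field_size_um
        for psd in self.psds:
            if psd.linked_bouton_id is not None and psd.linked_bouton_id not in bouton_ids:
                raise ParameterError(f"PSD {psd.id} links unknown bouton")
            for aid in psd.linked_astro_ids:
                if aid not in astro_ids:
                    raise ParameterError(f"PSD {psd.id} links unknown astro domain")
            x, y = psd.centre_um
            if not (0 <= x <= w and 0 <= y <= h):
                raise ParameterError(f"PSD {psd.id} centre outside field")


@dataclass
class RenderSpec:
    """How a scene is imaged: grid, PSF and noise.

    ``psf_fwhm_nm = 0`` renders with a delta PSF (no blurring beyond the
    object's own profile) — useful for closed-form checks.
    """

    modality: str = "highres"
    pixel_size_nm: float = HIGHRES_PIXEL_NM
    psf_fwhm_nm: float = HIGHRES_PSF_FWHM_NM
    poisson: bool = True
    read_noise_sd: float = 2.0
    bit_depth: int = 16
    max_pixels: int = 4096 * 4096

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel_size_nm must be positive")
        if self.psf_fwhm_nm < 0:
            raise ParameterError("psf_fwhm_nm must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")

    @classmethod
    def highres(cls, **kw) -> "RenderSpec":
        return cls(modality="highres", pixel_size_nm=HIGHRES_PIXEL_NM,
                   psf_fwhm_nm=HIGHRES_PSF_FWHM_NM, **kw)

    @classmethod
    def confocal(cls, **kw) -> "RenderSpec":
        return cls(modality="confocal", pixel_size_nm=STED_PIXEL_NM,
                   psf_fwhm_nm=CONFOCAL_PSF_FWHM_NM, **kw)

    @classmethod
    def sted(cls, **kw) -> "RenderSpec":
        return cls(modality="sted", pixel_size_nm=STED_PIXEL_NM,
                   psf_fwhm_nm=STED_PSF_FWHM_NM, **kw)


# ---------------------------------------------------------------------------
# generation

def _dart_throw(rng, n, lo, hi, min_sep, max_tries=200):
    """Uniform points in the box [lo, hi]² with a minimum separation."""
    if min_sep <= 0:
        return list(rng.uniform(lo, hi, size=(n, 2)))
    pts: list[np.ndarray] = []
    for _ in range(n):
        for _ in range(max_tries):
            p = rng.uniform(lo, hi, size=2)
            if all(np.hypot(*(p - q)) >= min_sep for q in pts):
                pts.append(p)
                break
        # if the field saturates, silently stop placing further objects
    return pts


_SPOKE_MIN_ANGLE_RAD = np.deg2rad(110.0)


def _nc_offsets(rng, n, disc_radius_nm, min_sep_nm, max_tries=500):
    """Offsets (nm) of n nanoclusters, hub-and-spoke around the PSD centre.

    The first NC (hub) sits at the centre; siblings (spokes) fall in the
    annulus between ``min_sep_nm`` and ``disc_radius_nm`` with at least
    110° of angular separation between spokes.  This keeps every sibling
    adjacent to the hub — so the diffraction-limited PSD stays one
    connected blob — while spoke–spoke chords stay long enough for STED
    to resolve each NC.
    """
    offs = [np.zeros(2)]
    angles: list[float] = []
    while len(offs) < n:
        placed = False
        for _ in range(max_tries):
            r = rng.uniform(min_sep_nm, disc_radius_nm)
            th = rng.uniform(0, 2 * np.pi)
            ang_ok = all(
                min(abs(th - a), 2 * np.pi - abs(th - a)) >= _SPOKE_MIN_ANGLE_RAD
                for a in angles
            )
            if ang_ok:
                offs.append(np.array([r * np.cos(th), r * np.sin(th)]))
                angles.append(th)
                placed = True
                break
        if not placed:  # geometrically saturated disc; keep what fits
            break
    return offs, angles


def _lognormal(rng, median, sigma_log):
    return float(median * np.exp(rng.normal(0.0, sigma_log)))


def _ellipse_radius_nm(nc: NCTruth, theta: float) -> float:
    """Distance from an NC's centre to its half-maximum contour along theta."""
    a = nc.long_axis_nm / 2.0
    b = nc.short_axis_nm / 2.0
    psi = theta - nc.orientation_rad
    return a * b / np.hypot(b * np.cos(psi), a * np.sin(psi))


def generate_scene(params: SceneParams, seed: int) -> GroundTruthScene:
    """Draw a ground-truth scene under the given study conditions.

    Reproducible for a fixed ``(params, seed)`` pair.  The realised
    tripartite fraction is a binomial draw at ``tripartite_fraction``
    over the bouton-contacted PSDs, so it converges to the requested
    value as the PSD count grows.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    w, h = params.field_size_um
    area = w * h
    margin = min(params.edge_margin_um, w / 2, h / 2)

    n_psd = rng.poisson(params.psd_density_per_um2 * area)
    lo = np.array([margin, margin])
    hi = np.array([w - margin, h - margin])
    centres = _dart_throw(rng, n_psd, lo, hi, params.min_psd_sep_um)

    counts = np.array(sorted(params.nc_count_probs), dtype=int)
    probs = np.array([params.nc_count_probs[k] for k in counts], dtype=float)
    mix_classes = sorted(params.bouton_class_mix)
    mix_probs = np.array([params.bouton_class_mix[c] for c in mix_classes])

    psds: list[PSDTruth] = []
    boutons: list[BoutonTruth] = []
    astros: list[AstroTruth] = []

    for pid, centre in enumerate(centres):
        n_nc = int(rng.choice(counts, p=probs))
        offs, spoke_angles = _nc_offsets(
            rng, n_nc, params.nc_disc_radius_nm, params.min_nc_sep_nm
        )
        ncs = []
        for j, off in enumerate(offs):
            long_ax = _lognormal(rng, params.nc_long_axis_median_nm,
                                 params.nc_long_axis_sigma_log)
            short_ax = _lognormal(rng, params.nc_short_axis_median_nm,
                                  params.nc_short_axis_sigma_log)
            if short_ax > long_ax:
                short_ax, long_ax = long_ax, short_ax
            if j == 0:
                if len(offs) == 1:
                    orientation = float(rng.uniform(0, np.pi))
                else:
                    # hub long axis kept away from every spoke direction,
                    # for the same resolvability reason as the spokes
                    cand = rng.uniform(0, np.pi, size=36)
                    axes = np.array(spoke_angles) % np.pi

                    def ax_dist(a):
                        d = np.abs(a - axes) % np.pi
                        return np.minimum(d, np.pi - d).min()

                    orientation = float(max(cand, key=ax_dist))
            else:
                # spokes lie tangentially (long axis ⊥ hub direction,
                # ±15° jitter) so the hub–spoke dip is governed by the
                # short axis and every sibling stays STED-resolvable
                orientation = float(
                    spoke_angles[j - 1] + np.pi / 2
                    + rng.uniform(-np.deg2rad(15), np.deg2rad(15))
                ) % np.pi
            ncs.append(NCTruth(
                centre_um=tuple(centre + off / 1000.0),
                short_axis_nm=short_ax,
                long_axis_nm=long_ax,
                orientation_rad=orientation,
                amplitude=_lognormal(rng, params.nc_amplitude_median,
                                     params.nc_amplitude_sigma_log),
            ))
        psd = PSDTruth(id=pid, centre_um=tuple(centre), nc_list=ncs)

        def _contact_point(diameter_nm):
            """Centre (µm) of a partner apposed to a random NC's edge."""
            nc = ncs[int(rng.integers(len(ncs)))]
            th = float(rng.uniform(0, 2 * np.pi))
            gap = rng.uniform(0, params.contact_gap_max_nm)
            dist = _ellipse_radius_nm(nc, th) + gap + diameter_nm / 2.0
            off = dist * np.array([np.cos(th), np.sin(th)])
            return np.asarray(nc.centre_um) + off / 1000.0, th

        has_bouton = rng.uniform() < params.synapse_fraction
        if has_bouton:
            bclass = str(rng.choice(mix_classes, p=mix_probs))
            if bclass == "vglut2":
                n_sub = int(rng.integers(1, 4))
                med = params.vglut2_diameter_median_nm
            else:
                n_sub = int(rng.integers(1, 3))
                med = params.vglut1_diameter_median_nm
            subs = []
            anchor = None
            for j in range(n_sub):
                d = _lognormal(rng, med, params.bouton_diameter_sigma_log)
                if j == 0:
                    # first substructure apposed across the cleft
                    anchor, th = _contact_point(d)
                    c_sub = anchor
                else:
                    jitter = rng.uniform(-1, 1, size=2) * d * 0.8
                    c_sub = anchor + (d * np.array([np.cos(th), np.sin(th)])
                                      + jitter) / 1000.0
                subs.append(BoutonSubstructure(
                    centre_um=tuple(c_sub),
                    diameter_nm=d,
                    amplitude=_lognormal(rng, params.bouton_amplitude_median,
                                         params.bouton_diameter_sigma_log),
                ))
            bid = len(boutons)
            boutons.append(BoutonTruth(bid, bclass, subs))
            psd.linked_bouton_id = bid

        attach_astro = (
            rng.uniform() < params.tripartite_fraction if has_bouton
            else rng.uniform() < params.astro_only_fraction
        )
        if attach_astro:
            d = _lognormal(rng, params.astro_diameter_median_nm,
                           params.astro_diameter_sigma_log)
            c_astro, _ = _contact_point(d)
            aid = len(astros)
            astros.append(AstroTruth(
                id=aid,
                centre_um=tuple(c_astro),
                diameter_nm=d,
                amplitude=_lognormal(rng, params.astro_amplitude_median,
                                     params.astro_diameter_sigma_log),
                linked_psd_id=pid,
            ))
            psd.linked_astro_ids.append(aid)

        psds.append(psd)

    n_decoy = rng.poisson(params.decoy_astro_density_per_um2 * area)
    for _ in range(n_decoy):
        aid = len(astros)
        astros.append(AstroTruth(
            id=aid,
            centre_um=tuple(rng.uniform(lo, hi)),
            diameter_nm=_lognormal(rng, params.astro_diameter_median_nm,
                                   params.astro_diameter_sigma_log),
            amplitude=_lognormal(rng, params.astro_amplitude_median,
                                 params.astro_diameter_sigma_log),
            linked_psd_id=None,
        ))

    return GroundTruthScene(
        field_size_um=tuple(params.field_size_um),
        psds=psds,
        boutons=boutons,
        astro_domains=astros,
        background_rate=params.background_rate,
        seed=seed,
        params=params,
    )


# ---------------------------------------------------------------------------
# rendering

def _gaussian_blobs_for_channel(scene: GroundTruthScene, channel: str):
    """(centre_um, cov_nm² matrix entries, amplitude) for each emitter."""
    blobs = []

    def circ(c, d, a):
        s2 = fwhm_to_sigma(d) ** 2
        blobs.append((np.asarray(c), s2, s2, 0.0, a))

    if channel == "psd95":
        for psd in scene.psds:
            for nc in psd.nc_list:
                ss = fwhm_to_sigma(nc.short_axis_nm) ** 2
                sl = fwhm_to_sigma(nc.long_axis_nm) ** 2
                c, s = np.cos(nc.orientation_rad), np.sin(nc.orientation_rad)
                # covariance of R·diag(sl, ss)·Rᵀ, long axis along orientation
                sxx = sl * c * c + ss * s * s
                syy = sl * s * s + ss * c * c
                sxy = (sl - ss) * c * s
                blobs.append((np.asarray(nc.centre_um), sxx, syy, sxy,
                              nc.amplitude))
    elif channel in ("vglut1", "vglut2"):
        for b in scene.boutons:
            if b.bouton_class == channel:
                for sub in b.substructures:
                    circ(sub.centre_um, sub.diameter_nm, sub.amplitude)
    elif channel == "astro":
        for a in scene.astro_domains:
            circ(a.centre_um, a.diameter_nm, a.amplitude)
    else:
        raise ParameterError(f"unknown channel {channel!r}")
    return blobs


def render_channel(
    scene: GroundTruthScene,
    channel: str,
    spec: RenderSpec,
    seed: int,
) -> ChannelImage:
    """Render one channel of a scene onto a pixel grid.

    The noiseless image is the sum of the objects' Gaussian profiles
    convolved (analytically) with the Gaussian PSF, sampled at pixel
    centres and scaled by pixel area, plus the constant background.
    Poisson shot noise and additive Gaussian read noise follow, clipped
    to the bit depth.  Deterministic for a fixed seed.
    """
    px_nm = spec.pixel_size_nm
    w_um, h_um = scene.field_size_um
    n_cols = int(np.ceil(w_um * 1000.0 / px_nm))
    n_rows = int(np.ceil(h_um * 1000.0 / px_nm))
    if n_rows * n_cols > spec.max_pixels:
        raise ParameterError(
            f"render grid {n_rows}x{n_cols} exceeds max_pixels={spec.max_pixels}"
        )

    img = np.full((n_rows, n_cols), float(scene.background_rate))
    psf_var = fwhm_to_sigma(spec.psf_fwhm_nm) ** 2
    px_area = px_nm * px_nm

    for centre_um, sxx, syy, sxy, amp in _gaussian_blobs_for_channel(scene, channel):
        sxx, syy = sxx + psf_var, syy + psf_var
        det = sxx * syy - sxy * sxy
        norm = amp * px_area / (2.0 * np.pi * np.sqrt(det))
        cx_nm, cy_nm = centre_um[0] * 1000.0, centre_um[1] * 1000.0
        # 6-sigma support window (truncation error < 2e-8 of the mass)
        smax = np.sqrt(max(sxx, syy))
        r0 = max(int((cy_nm - 6 * smax) / px_nm), 0)
        r1 = min(int((cy_nm + 6 * smax) / px_nm) + 2, n_rows)
        c0 = max(int((cx_nm - 6 * smax) / px_nm), 0)
        c1 = min(int((cx_nm + 6 * smax) / px_nm) + 2, n_cols)
        if r0 >= r1 or c0 >= c1:
            continue
        ys = (np.arange(r0, r1) + 0.5) * px_nm - cy_nm
        xs = (np.arange(c0, c1) + 0.5) * px_nm - cx_nm
        X, Y = np.meshgrid(xs, ys)
        # quadratic form of the inverse covariance
        q = (syy * X * X - 2.0 * sxy * X * Y + sxx * Y * Y) / det
        img[r0:r1, c0:c1] += norm * np.exp(-0.5 * q)

    rng = np.random.default_rng(seed)
    if spec.poisson:
        img = rng.poisson(img).astype(float)
    if spec.read_noise_sd > 0:
        img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 2.0 ** spec.bit_depth - 1)

    return ChannelImage(img, pixel_size_nm=px_nm, modality=spec.modality,
                        label=channel)


# ---------------------------------------------------------------------------
# truth bookkeeping

def truth_summary(scene: GroundTruthScene) -> pd.DataFrame:
    """Per-PSD ground truth table: the oracle for recovery tests.

    Columns: psd_id, x_um, y_um, nc_count, nc_class, has_bouton,
    bouton_class, has_astro, tripartite, lamina_label.
    """
    rows = []
    bclass = {b.id: b.bouton_class for b in scene.boutons}
    for psd in scene.psds:
        n = len(psd.nc_list)
        has_b = psd.linked_bouton_id is not None
        has_a = len(psd.linked_astro_ids) > 0
        rows.append({
            "psd_id": psd.id,
            "x_um": psd.centre_um[0],
            "y_um": psd.centre_um[1],
            "nc_count": n,
            "nc_class": "1NC" if n == 1 else ("2NC" if n == 2 else "3plusNC"),
            "has_bouton": has_b,
            "bouton_class": bclass.get(psd.linked_bouton_id),
            "has_astro": has_a,
            "tripartite": has_b and has_a,
            "lamina_label": psd.lamina_label,
        })
    return pd.DataFrame(
        rows,
        columns=["psd_id", "x_um", "y_um", "nc_count", "nc_class",
                 "has_bouton", "bouton_class", "has_astro", "tripartite",
                 "lamina_label"],
    )


# ---------------------------------------------------------------------------
# scene (de)serialisation

def scene_to_json(scene: GroundTruthScene, path) -> None:
    """Write a scene (objects, links, parameters, seed) as JSON."""
    doc = {
        "field_size_um": list(scene.field_size_um),
        "background_rate": scene.background_rate,
        "seed": scene.seed,
        "params": asdict(scene.params) if scene.params is not None else None,
        "psds": [
            {
                "id": p.id,
                "centre_um": list(p.centre_um),
                "lamina_label": p.lamina_label,
                "linked_bouton_id": p.linked_bouton_id,
                "linked_astro_ids": list(p.linked_astro_ids),
                "nc_list": [
                    {
                        "centre_um": list(nc.centre_um),
                        "short_axis_nm": nc.short_axis_nm,
                        "long_axis_nm": nc.long_axis_nm,
                        "orientation_rad": nc.orientation_rad,
                        "amplitude": nc.amplitude,
                    }
                    for nc in p.nc_list
                ],
            }
            for p in scene.psds
        ],
        "boutons": [
            {
                "id": b.id,
                "bouton_class": b.bouton_class,
                "substructures": [asdict(s) for s in b.substructures],
            }
            for b in scene.boutons
        ],
        "astro_domains": [asdict(a) for a in scene.astro_domains],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def scene_from_json(path) -> GroundTruthScene:
    with open(path) as fh:
        doc = json.load(fh)
    psds = [
        PSDTruth(
            id=p["id"],
            centre_um=tuple(p["centre_um"]),
            nc_list=[
                NCTruth(
                    centre_um=tuple(nc["centre_um"]),
                    short_axis_nm=nc["short_axis_nm"],
                    long_axis_nm=nc["long_axis_nm"],
                    orientation_rad=nc["orientation_rad"],
                    amplitude=nc["amplitude"],
                )
                for nc in p["nc_list"]
            ],
            lamina_label=p["lamina_label"],
            linked_bouton_id=p["linked_bouton_id"],
            linked_astro_ids=list(p["linked_astro_ids"]),
        )
        for p in doc["psds"]
    ]
    boutons = [
        BoutonTruth(
            id=b["id"],
            bouton_class=b["bouton_class"],
            substructures=[
                BoutonSubstructure(
                    centre_um=tuple(s["centre_um"]),
                    diameter_nm=s["diameter_nm"],
                    amplitude=s["amplitude"],
                )
                for s in b["substructures"]
            ],
        )
        for b in doc["boutons"]
    ]
    astros = [
        AstroTruth(
            id=a["id"],
            centre_um=tuple(a["centre_um"]),
            diameter_nm=a["diameter_nm"],
            amplitude=a["amplitude"],
            linked_psd_id=a["linked_psd_id"],
        )
        for a in doc["astro_domains"]
    ]
    params = SceneParams(**{
        **doc["params"],
        "field_size_um": tuple(doc["params"]["field_size_um"]),
        "nc_count_probs": {int(k): v
                           for k, v in doc["params"]["nc_count_probs"].items()},
    }) if doc.get("params") else None
    return GroundTruthScene(
        field_size_um=tuple(doc["field_size_um"]),
        psds=psds,
        boutons=boutons,
        astro_domains=astros,
        background_rate=doc["background_rate"],
        seed=doc["seed"],
        params=params,
    )
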
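"""Synthetic fluorescence-microscopy data with known ground truth.

Every generator in this module emulates one acquisition modality of a
tRNA-FRET translation-imaging experiment in mixed neuron/glia culture:

* :func:`make_neuron_geometry` — schematic compartment masks (soma disk,
  dendrite tubes with centerlines, a glial annulus).
* :func:`simulate_fret_channels` — donor (Cy3) / acceptor (Cy5) / raw-FRET
  widefield channels with planted bleed-through and cross-excitation
  coefficients, plus the single-label control stacks used for calibration.
* :func:`simulate_localizations` — three-channel SMLM point clouds with a
  bimodal local-density structure (clustered patches over a diffuse
  background) and planted multicolor region overlap.
* :func:`simulate_tracks` — run-and-pause particle trajectories at the slow
  axonal-transport velocity scale, 1D along dendrites and 2D elsewhere.
* :func:`simulate_puncta_population` / :func:`apply_puromycin_dissociation`
  — log-normal puncta-size populations quantized into signal units, and the
  puromycin perturbation that splits large puncta while conserving total
  signal units exactly.

Each simulator returns a ground-truth record holding every planted
parameter so that the analysis modules can be validated by parameter
recovery.  All randomness flows from the seed in :class:`SimConfig` (or an
explicitly passed generator); identical configuration and seed reproduce
identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk

__all__ = [
    "SimConfig",
    "CompartmentMasks",
    "ChannelStack",
    "FretSimConfig",
    "FretGroundTruth",
    "LocalizationSimSpec",
    "LocSimGroundTruth",
    "MotionConfig",
    "MotionGroundTruth",
    "PunctaDistConfig",
    "SplitConfig",
    "Track",
    "TrackSet",
    "BACKGROUND",
    "GLIA",
    "SOMA",
    "DENDRITE",
    "COMPARTMENT_NAMES",
    "make_neuron_geometry",
    "simulate_fret_channels",
    "simulate_localizations",
    "simulate_tracks",
    "simulate_puncta_population",
    "apply_puromycin_dissociation",
]

# compartment label codes
BACKGROUND, GLIA, SOMA, DENDRITE = 0, 1, 2, 3
COMPARTMENT_NAMES = {BACKGROUND: "background", GLIA: "glia", SOMA: "soma", DENDRITE: "dendrite"}

#: velocity medians (nm/s) per compartment used as simulation defaults
DEFAULT_SPEED_MEDIAN_NM_S = {"soma": 22.16, "glia": 20.77, "dendrite": 15.49}
#: log-sd of the log-normal speed distribution, derived from the reported
#: inter-quartile ranges (sigma = ln(q3/q1) / (2 * 0.6745))
DEFAULT_SPEED_SIGMA_LOG = {
    "soma": math.log(26.02 / 18.28) / (2 * 0.674489750196082),
    "glia": math.log(23.68 / 17.35) / (2 * 0.674489750196082),
    "dendrite": math.log(19.86 / 11.10) / (2 * 0.674489750196082),
}


@dataclass
class SimConfig:
    """Global simulation configuration shared by all generators.

    Parameters
    ----------
    image_size:
        (height, width) in pixels.
    pixel_size_nm:
        Physical pixel size; default 108 nm (widefield camera sampling).
    n_frames:
        Number of time frames for time-lapse simulations (default 30).
    frame_interval_s:
        Acquisition interval in seconds (default 60 s).
    seed:
        Seed for the single NumPy generator that drives all randomness.
    soma_radius_px, n_dendrites, dendrite_width_px, dendrite_length_px:
        Schematic neuron geometry.
    glia_width_px:
        Radial width of the glial annulus surrounding the neuron.
    photon_scale:
        Photons per intensity unit for Poisson shot noise; ``None`` disables
        shot noise (noiseless oracle mode).
    read_noise_sd:
        Gaussian read noise SD in intensity units (0 disables).
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 108.0
    n_frames: int = 30
    frame_interval_s: float = 60.0
    seed: int = 0
    soma_radius_px: float = 25.0
    n_dendrites: int = 4
    dendrite_width_px: float = 7.0
    dendrite_length_px: float = 80.0
    glia_width_px: float = 20.0
    photon_scale: float | None = None
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class CompartmentMasks:
    """Compartment label image plus dendrite centerlines.

    ``labels`` holds mutually exclusive classes (BACKGROUND, GLIA, SOMA,
    DENDRITE). ``centerlines`` is one ``(n, 2)`` float array of (row, col)
    pixel coordinates per dendrite, ordered from the soma boundary outward.
    """

    labels: np.ndarray
    centerlines: list[np.ndarray]
    soma_center: tuple[float, float]
    pixel_size_nm: float

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def neuron_mask(self) -> np.ndarray:
        return (self.labels == SOMA) | (self.labels == DENDRITE)


@dataclass
class ChannelStack:
    """Registered multi-channel widefield image set (one 2D image each)."""

    donor: np.ndarray
    acceptor: np.ndarray
    fret: np.ndarray
    marker: np.ndarray | None = None
    pixel_size_nm: float = 108.0


def make_neuron_geometry(cfg: SimConfig) -> CompartmentMasks:
    """Build a schematic neuron: disk soma, straight radial dendrites, a
    glial annulus around the neuron, the rest background.

    Dendrite directions are evenly spaced with a seeded angular jitter;
    each dendrite is rasterized as a tube of ``dendrite_width_px`` around
    its centerline.  Raises ``ValueError`` naming the violated dimension if
    the geometry does not fit the image.
    """
    h, w = cfg.image_size
    half = min(h, w) / 2.0
    extent = cfg.soma_radius_px + cfg.dendrite_length_px
    if extent + 1 > half:
        raise ValueError(
            f"soma_radius_px + dendrite_length_px = {extent:.1f} px does not fit "
            f"inside min(image_size)/2 = {half:.1f} px"
        )
    rng = cfg.rng()
    labels = np.zeros((h, w), dtype=np.uint8)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)

    # glial annulus just beyond the neuron's reach
    glia_in = extent + 2.0
    glia_out = min(glia_in + cfg.glia_width_px, half - 0.5)
    if glia_out > glia_in:
        labels[(r >= glia_in) & (r <= glia_out)] = GLIA

    # soma disk
    rr, cc = draw_disk((cy, cx), cfg.soma_radius_px, shape=(h, w))
    labels[rr, cc] = SOMA

    # dendrites: evenly spaced base angles + jitter, straight tubes
    centerlines: list[np.ndarray] = []
    n_d = int(cfg.n_dendrites)
    if n_d > 0:
        base = np.linspace(0, 2 * np.pi, n_d, endpoint=False)
        jitter = rng.uniform(-0.25, 0.25, size=n_d)
        angles = base + jitter + rng.uniform(0, 2 * np.pi)
        for ang in angles:
            t = np.arange(0.0, cfg.dendrite_length_px + 0.5, 0.5)
            rows = cy + (cfg.soma_radius_px + t) * np.sin(ang)
            cols = cx + (cfg.soma_radius_px + t) * np.cos(ang)
            line = np.column_stack([rows, cols])
            centerlines.append(line[::2].copy())  # 1 px sampling for the stored polyline
            canvas = np.ones((h, w), dtype=bool)
            ri = np.clip(np.round(rows).astype(int), 0, h - 1)
            ci = np.clip(np.round(cols).astype(int), 0, w - 1)
            canvas[ri, ci] = False
            dist = ndimage.distance_transform_edt(canvas)
            tube = dist <= cfg.dendrite_width_px / 2.0
            labels[tube & (labels != SOMA)] = DENDRITE

    return CompartmentMasks(labels=labels, centerlines=centerlines,
                            soma_center=(cy, cx), pixel_size_nm=cfg.pixel_size_nm)


# ---------------------------------------------------------------------------
# FRET channel simulation
# ---------------------------------------------------------------------------

@dataclass
class FretSimConfig:
    """Planted FRET/crosstalk truth for :func:`simulate_fret_channels`.

    ``a_donor_bleed`` is the fraction of donor (Cy3) intensity leaking into
    the raw-FRET channel (bleed-through); ``b_acceptor_cross`` the fraction
    of acceptor (Cy5) intensity appearing there via direct cross-excitation.
    ``fret_fraction`` is the per-punctum true FRET fraction f in [0, 1]: the
    planted FRET-channel signal is f * (donor + acceptor) / 2 within each
    punctum, so a noiseless, crosstalk-corrected analysis reads back
    cFRET(%) = 100 f.
    """

    a_donor_bleed: float = 0.25
    b_acceptor_cross: float = 0.10
    fret_fraction: float | Sequence[float] = 0.3
    n_puncta: int = 200
    spot_sigma_px: float = 1.3
    donor_amplitude: float = 400.0
    acceptor_amplitude: float = 400.0
    amplitude_gsd: float = 1.5
    compartments: tuple[int, ...] = (SOMA, DENDRITE)
    min_separation_px: float = 0.0   # > 0 keeps puncta resolvable as spots

    def __post_init__(self) -> None:
        for name, v in (("a_donor_bleed", self.a_donor_bleed),
                        ("b_acceptor_cross", self.b_acceptor_cross)):
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1), got {v}")


@dataclass
class FretGroundTruth:
    a_donor_bleed: float
    b_acceptor_cross: float
    fret_fraction: np.ndarray          # per punctum, in [0, 1]
    positions: np.ndarray              # (n, 2) row/col
    donor_amplitudes: np.ndarray
    acceptor_amplitudes: np.ndarray
    spot_sigma_px: float


def _render_spots(shape: tuple[int, int], positions: np.ndarray,
                  amplitudes: np.ndarray, sigma: float) -> np.ndarray:
    """Sum of isotropic Gaussian spots; amplitude is the peak value."""
    img = np.zeros(shape, dtype=float)
    rad = max(2, int(math.ceil(4 * sigma)))
    h, w = shape
    for (r0, c0), amp in zip(positions, amplitudes):
        r0i, c0i = int(round(r0)), int(round(c0))
        rlo, rhi = max(0, r0i - rad), min(h, r0i + rad + 1)
        clo, chi = max(0, c0i - rad), min(w, c0i + rad + 1)
        if rlo >= rhi or clo >= chi:
            continue
        yy, xx = np.mgrid[rlo:rhi, clo:chi]
        img[rlo:rhi, clo:chi] += amp * np.exp(
            -((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sigma ** 2))
    return img


def _apply_noise(img: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    out = img
    if cfg.photon_scale is not None and cfg.photon_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * cfg.photon_scale) / cfg.photon_scale
    if cfg.read_noise_sd > 0:
        out = out + rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
    return np.asarray(out, dtype=float)


def simulate_fret_channels(
    masks: CompartmentMasks,
    truth_cfg: FretSimConfig,
    cfg: SimConfig,
) -> tuple[ChannelStack, ChannelStack, ChannelStack, FretGroundTruth]:
    """Simulate a double-labeled sample plus the two single-label controls.

    Returns ``(sample, donor_only, acceptor_only, truth)``.  In every stack
    the raw-FRET channel is built as

        raw = true_FRET + a * donor + b * acceptor (+ noise)

    with ``true_FRET = f * (donor + acceptor) / 2`` per punctum.  The
    control stacks contain only one dye species each, so their raw-FRET
    channel carries pure leakage — exactly the calibration measurement
    performed on single-label control wells.
    """
    rng = cfg.rng()
    h, w = masks.labels.shape
    allowed = np.isin(masks.labels, truth_cfg.compartments)
    coords = np.argwhere(allowed)
    if coords.shape[0] == 0:
        raise ValueError("no pixels in the requested compartments to place puncta")
    if truth_cfg.min_separation_px > 0:
        # greedy thinning: draw candidates, keep those far enough apart
        order = rng.permutation(coords.shape[0])
        kept: list[np.ndarray] = []
        d2min = truth_cfg.min_separation_px ** 2
        for ci in order:
            p = coords[ci]
            if all(((p - q) ** 2).sum() >= d2min for q in kept):
                kept.append(p)
                if len(kept) == truth_cfg.n_puncta:
                    break
        if len(kept) < truth_cfg.n_puncta:
            raise ValueError(
                f"could only place {len(kept)} of {truth_cfg.n_puncta} puncta at "
                f"min separation {truth_cfg.min_separation_px} px")
        positions = np.array(kept, dtype=float)
    else:
        idx = rng.choice(coords.shape[0], size=truth_cfg.n_puncta, replace=True)
        positions = coords[idx].astype(float)
    positions = positions + rng.uniform(-0.4, 0.4, size=(truth_cfg.n_puncta, 2))

    log_sd = math.log(truth_cfg.amplitude_gsd) if truth_cfg.amplitude_gsd > 1 else 0.0
    amp_d = truth_cfg.donor_amplitude * np.exp(rng.normal(0, log_sd, truth_cfg.n_puncta))
    amp_a = truth_cfg.acceptor_amplitude * np.exp(rng.normal(0, log_sd, truth_cfg.n_puncta))

    f = np.broadcast_to(np.asarray(truth_cfg.fret_fraction, dtype=float),
                        (truth_cfg.n_puncta,)).copy()
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fret_fraction must lie in [0, 1]")

    sigma = truth_cfg.spot_sigma_px
    donor = _render_spots((h, w), positions, amp_d, sigma)
    acceptor = _render_spots((h, w), positions, amp_a, sigma)
    fret_true = _render_spots((h, w), positions, f * (amp_d + amp_a) / 2.0, sigma)

    a, b = truth_cfg.a_donor_bleed, truth_cfg.b_acceptor_cross
    marker = masks.neuron_mask.astype(float) * 100.0

    def stack(d: np.ndarray, ac: np.ndarray, ft: np.ndarray) -> ChannelStack:
        raw = ft + a * d + b * ac
        return ChannelStack(
            donor=_apply_noise(d, cfg, rng),
            acceptor=_apply_noise(ac, cfg, rng),
            fret=_apply_noise(raw, cfg, rng),
            marker=marker,
            pixel_size_nm=cfg.pixel_size_nm,
        )

    zeros = np.zeros((h, w))
    sample = stack(donor, acceptor, fret_true)
    donor_only = stack(donor, zeros, zeros)
    acceptor_only = stack(zeros, acceptor, zeros)
    truth = FretGroundTruth(
        a_donor_bleed=a, b_acceptor_cross=b, fret_fraction=f,
        positions=positions, donor_amplitudes=amp_d, acceptor_amplitudes=amp_a,
        spot_sigma_px=sigma,
    )
    return sample, donor_only, acceptor_only, truth


# ---------------------------------------------------------------------------
# SMLM localization simulation
# ---------------------------------------------------------------------------

@dataclass
class LocalizationSimSpec:
    """Planted structure for the three-channel SMLM simulation.

    Clustered localizations live in circular patches; channels share or
    disjoin whole patches, which makes the region-level (Jaccard) overlap
    between channels controllable.  Diffuse localizations are scattered
    uniformly outside all patches.  Densities are localizations per nm².
    """

    field_size_nm: tuple[float, float] = (2000.0, 2000.0)
    channels: tuple[str, str, str] = ("rpS6", "rpL10a", "tRNA")
    pairwise_overlap: float = 0.45
    triple_overlap: float = 0.25
    patches_per_channel: int = 12
    patch_radius_nm: float = 150.0
    clustered_density: float = 0.010
    diffuse_density: float = 0.001
    min_mode_ratio: float = 4.0

    def __post_init__(self) -> None:
        if not (0 <= self.triple_overlap <= 1 and 0 <= self.pairwise_overlap <= 1):
            raise ValueError("overlap fractions must lie in [0, 1]")
        if self.triple_overlap > self.pairwise_overlap:
            raise ValueError(
                f"infeasible overlap spec: triple ({self.triple_overlap}) exceeds "
                f"pairwise ({self.pairwise_overlap})")
        if self.clustered_density < self.min_mode_ratio * self.diffuse_density:
            raise ValueError(
                "clustered_density must exceed diffuse_density by at least "
                f"min_mode_ratio = {self.min_mode_ratio}")


@dataclass
class LocSimGroundTruth:
    labels: dict[str, np.ndarray]          # per channel: "clustered"/"diffuse" per row
    planted_pairwise: dict[tuple[str, str], float]
    planted_triple: float
    requested_pairwise: float
    requested_triple: float
    overlap_tolerance: float               # max |planted - requested|
    clustered_density: float
    diffuse_density: float
    patch_centers: np.ndarray              # (P, 2) x/y nm
    patch_radius_nm: float
    patch_membership: np.ndarray           # (P, 3) bool, column per channel


def _solve_patch_allocation(m: int, j2: float, j3: float) -> dict[str, int]:
    """Integer Venn-class patch counts for three channels with m patches
    each, targeting pairwise Jaccard j2 (all pairs) and triple Jaccard j3.

    With I = |pairwise intersection| (same for each pair by symmetry) and
    t = |triple intersection|: J2 = I/(2m - I) and, by inclusion-exclusion,
    J3 = t/(3m - 3I + t).
    """
    if j2 >= 1.0:
        if j3 < 1.0 and j3 > 0:
            # all pairs identical forces the triple to be identical too
            raise ValueError("pairwise overlap 1 with triple < 1 is infeasible")
        return {"t": m, "d": 0, "s": 0}
    I = int(round(2 * m * j2 / (1 + j2)))
    if j3 >= 1.0:
        raise ValueError("triple overlap 1 requires pairwise overlap 1")
    t = int(round(j3 * (3 * m - 3 * I) / (1 - j3)))
    t = min(t, I)
    d = I - t
    s = m - 2 * d - t
    if s < 0 or d < 0 or t < 0:
        raise ValueError(
            f"infeasible overlap spec: needs {2 * d + t} shared patches per channel "
            f"but only {m} available; reduce overlaps or raise patches_per_channel")
    return {"t": t, "d": d, "s": s}


def simulate_localizations(
    cfg: SimConfig,
    spec: LocalizationSimSpec,
) -> tuple[dict[str, pd.DataFrame], LocSimGroundTruth]:
    """Simulate three SMLM channels with planted density bimodality and
    planted region overlap.

    Returns a dict of per-channel localization tables (columns ``id, frame,
    x_nm, y_nm, channel, uncertainty_nm``) and the ground truth, which
    records the *achieved* region-overlap fractions (integer patch counts
    cannot always hit the request exactly; the gap is reported as
    ``overlap_tolerance``).
    """
    rng = cfg.rng()
    W, H = spec.field_size_nm
    m = spec.patches_per_channel
    alloc = _solve_patch_allocation(m, spec.pairwise_overlap, spec.triple_overlap)
    t, d, s = alloc["t"], alloc["d"], alloc["s"]

    # membership rows: triple patches, one block of pairwise-only patches per
    # pair, one exclusive block per channel
    membership: list[tuple[bool, bool, bool]] = []
    membership += [(True, True, True)] * t
    membership += [(True, True, False)] * d
    membership += [(True, False, True)] * d
    membership += [(False, True, True)] * d
    membership += [(True, False, False)] * s
    membership += [(False, True, False)] * s
    membership += [(False, False, True)] * s
    P = len(membership)
    member = np.array(membership, dtype=bool)

    # non-overlapping patch placement on a shuffled grid
    cell = 2 * spec.patch_radius_nm * 1.15
    nx, ny = int(W // cell), int(H // cell)
    if nx * ny < P:
        raise ValueError(
            f"field of {W}x{H} nm fits only {nx * ny} non-overlapping patches, "
            f"need {P}; enlarge field_size_nm or shrink patch_radius_nm")
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny))
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    rng.shuffle(cells)
    centers = (cells[:P] + 0.5) * cell + rng.uniform(
        -0.1 * spec.patch_radius_nm, 0.1 * spec.patch_radius_nm, size=(P, 2))

    patch_area = math.pi * spec.patch_radius_nm ** 2
    free_area = W * H - P * patch_area

    tables: dict[str, pd.DataFrame] = {}
    labels: dict[str, np.ndarray] = {}
    for ci, ch in enumerate(spec.channels):
        xs, ys, cls = [], [], []
        for p in np.flatnonzero(member[:, ci]):
            n_pts = rng.poisson(spec.clustered_density * patch_area)
            rr = spec.patch_radius_nm * np.sqrt(rng.uniform(size=n_pts))
            th = rng.uniform(0, 2 * math.pi, size=n_pts)
            xs.append(centers[p, 0] + rr * np.cos(th))
            ys.append(centers[p, 1] + rr * np.sin(th))
            cls.append(np.full(n_pts, "clustered"))
        # diffuse background outside every patch (rejection sampling)
        n_diff = rng.poisson(spec.diffuse_density * free_area)
        got_x, got_y = [], []
        need = n_diff
        while need > 0:
            cand = rng.uniform([0, 0], [W, H], size=(max(2 * need, 64), 2))
            d2 = ((cand[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            ok = (d2 > spec.patch_radius_nm ** 2).all(axis=1)
            keep = cand[ok][:need]
            got_x.append(keep[:, 0])
            got_y.append(keep[:, 1])
            need -= keep.shape[0]
        xs += got_x
        ys += got_y
        cls.append(np.full(n_diff, "diffuse"))
        x = np.concatenate(xs) if xs else np.empty(0)
        y = np.concatenate(ys) if ys else np.empty(0)
        c = np.concatenate(cls) if cls else np.empty(0, dtype=object)
        n = x.size
        tables[ch] = pd.DataFrame({
            "id": np.arange(n),
            "frame": rng.integers(0, max(cfg.n_frames, 1), size=n),
            "x_nm": x,
            "y_nm": y,
            "channel": ch,
            "uncertainty_nm": np.full(n, 20.0),
        })
        labels[ch] = c

    # achieved region overlaps from the integer allocation
    def jacc2(i: int, j: int) -> float:
        inter = int((member[:, i] & member[:, j]).sum())
        union = int((member[:, i] | member[:, j]).sum())
        return inter / union if union else float("nan")

    chs = spec.channels
    planted_pairwise = {
        (chs[i], chs[j]): jacc2(i, j) for i in range(3) for j in range(i + 1, 3)
    }
    inter3 = int(member.all(axis=1).sum())
    union3 = int(member.any(axis=1).sum())
    planted_triple = inter3 / union3 if union3 else float("nan")
    tol = max(
        max(abs(v - spec.pairwise_overlap) for v in planted_pairwise.values()),
        abs(planted_triple - spec.triple_overlap),
    )
    truth = LocSimGroundTruth(
        labels=labels,
        planted_pairwise=planted_pairwise,
        planted_triple=planted_triple,
        requested_pairwise=spec.pairwise_overlap,
        requested_triple=spec.triple_overlap,
        overlap_tolerance=tol,
        clustered_density=spec.clustered_density,
        diffuse_density=spec.diffuse_density,
        patch_centers=centers,
        patch_radius_nm=spec.patch_radius_nm,
        patch_membership=member,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Particle trajectories
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """One particle trajectory: strictly increasing frames and positions
    in nm; ``displacements`` are the per-step vectors (n-1, 2)."""

    frames: np.ndarray
    xy_nm: np.ndarray
    compartment: str | None = None
    track_id: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy_nm = np.asarray(self.xy_nm, dtype=float)
        if self.frames.size >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing within a track")

    @property
    def displacements(self) -> np.ndarray:
        return np.diff(self.xy_nm, axis=0)

    def __len__(self) -> int:
        return self.frames.size


@dataclass
class TrackSet:
    tracks: list[Track]
    frame_interval_s: float

    def __iter__(self):
        return iter(self.tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for f, (x, y) in zip(tr.frames, tr.xy_nm):
                rows.append((tr.track_id, int(f), x, y, tr.compartment))
        return pd.DataFrame(rows, columns=["track_id", "frame", "x_nm", "y_nm", "compartment"])


@dataclass
class MotionConfig:
    """Run-and-pause motion model.

    Particles alternate constant-velocity runs (speed drawn per run from a
    log-normal at the slow-transport scale) and pauses.  Dendritic motion is
    1D along an axis; somatic/glial motion is 2D with a random direction per
    run.  ``static_fraction`` particles never move.  ``sigma_loc_nm`` is the
    localization noise added to *reported* (detected) positions only.

    Pausing is off by default (``p_run_to_pause = 0``): particles then run
    continuously at their drawn speed, so the planted per-compartment
    log-normal median is also the median per-track mean instantaneous
    speed.  With pausing enabled, pauses dilute the per-track mean below
    the run-speed median.
    """

    n_particles: int = 100
    compartment: Literal["soma", "dendrite", "glia"] = "dendrite"
    speed_median_nm_s: float | None = None      # default: per-compartment table
    speed_sigma_log: float | None = None
    p_run_to_pause: float = 0.0
    p_pause_to_run: float = 0.30
    p_reverse: float = 0.5                      # direction flip at each new run
    static_fraction: float = 0.0
    sigma_loc_nm: float = 0.0

    def resolved_speed(self) -> tuple[float, float]:
        med = (self.speed_median_nm_s if self.speed_median_nm_s is not None
               else DEFAULT_SPEED_MEDIAN_NM_S[self.compartment])
        sig = (self.speed_sigma_log if self.speed_sigma_log is not None
               else DEFAULT_SPEED_SIGMA_LOG[self.compartment])
        return med, sig


@dataclass
class MotionGroundTruth:
    states: list[np.ndarray]               # per track, per step: "run"/"pause"
    displacements: list[np.ndarray]        # per track, (n-1, 2) true nm
    mean_speeds: np.ndarray                # per track, nm/s
    median_speed: float
    iqr: tuple[float, float]


def simulate_tracks(
    cfg: SimConfig,
    motion_cfg: MotionConfig,
) -> tuple[pd.DataFrame, TrackSet, MotionGroundTruth]:
    """Simulate run-and-pause trajectories.

    Returns ``(detections, tracks, truth)``: a per-frame detection table
    (``frame, x_nm, y_nm`` with localization noise applied), the true
    trajectories (noiseless positions), and the motion ground truth with
    every true displacement and the per-track mean instantaneous speeds.
    """
    if cfg.n_frames < 2:
        raise ValueError("n_frames must be >= 2 to form displacements")
    rng = cfg.rng()
    dt = cfg.frame_interval_s
    med, sig = motion_cfg.resolved_speed()
    mu = math.log(med)
    h_nm = cfg.image_size[0] * cfg.pixel_size_nm
    w_nm = cfg.image_size[1] * cfg.pixel_size_nm
    # keep starting positions away from the border so tracks stay in-field
    margin = 0.25
    n_static = int(round(motion_cfg.static_fraction * motion_cfg.n_particles))

    tracks: list[Track] = []
    states_all, disp_all = [], []
    for i in range(motion_cfg.n_particles):
        pos = rng.uniform([margin * w_nm, margin * h_nm],
                          [(1 - margin) * w_nm, (1 - margin) * h_nm])
        static = i < n_static
        if motion_cfg.compartment == "dendrite":
            ang = rng.uniform(0, 2 * math.pi)
            axis = np.array([math.cos(ang), math.sin(ang)])
        running = True
        speed = float(np.exp(rng.normal(mu, sig)))
        if motion_cfg.compartment == "dendrite":
            direction = axis * rng.choice([-1.0, 1.0])
        else:
            a = rng.uniform(0, 2 * math.pi)
            direction = np.array([math.cos(a), math.sin(a)])
        xs = [pos.copy()]
        st = []
        for _ in range(cfg.n_frames - 1):
            if static:
                st.append("pause")
                xs.append(xs[-1].copy())
                continue
            if running:
                if rng.uniform() < motion_cfg.p_run_to_pause:
                    running = False
            else:
                if rng.uniform() < motion_cfg.p_pause_to_run:
                    running = True
                    speed = float(np.exp(rng.normal(mu, sig)))
                    if motion_cfg.compartment == "dendrite":
                        if rng.uniform() < motion_cfg.p_reverse:
                            direction = -direction
                    else:
                        a = rng.uniform(0, 2 * math.pi)
                        direction = np.array([math.cos(a), math.sin(a)])
            if running:
                st.append("run")
                xs.append(xs[-1] + direction * speed * dt)
            else:
                st.append("pause")
                xs.append(xs[-1].copy())
        xy = np.vstack(xs)
        tracks.append(Track(frames=np.arange(cfg.n_frames), xy_nm=xy,
                            compartment=motion_cfg.compartment, track_id=i))
        states_all.append(np.array(st))
        disp_all.append(np.diff(xy, axis=0))

    mean_speeds = np.array([
        np.mean(np.linalg.norm(d, axis=1)) / dt for d in disp_all
    ])
    q1, q3 = np.percentile(mean_speeds, [25, 75])
    truth = MotionGroundTruth(
        states=states_all, displacements=disp_all, mean_speeds=mean_speeds,
        median_speed=float(np.median(mean_speeds)), iqr=(float(q1), float(q3)),
    )

    rows = []
    for tr in tracks:
        noisy = tr.xy_nm + rng.normal(0, motion_cfg.sigma_loc_nm, size=tr.xy_nm.shape) \
            if motion_cfg.sigma_loc_nm > 0 else tr.xy_nm
        for f, (x, y) in zip(tr.frames, noisy):
            rows.append((int(f), x, y))
    detections = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"])
    detections = detections.sort_values(["frame"], kind="stable").reset_index(drop=True)
    return detections, TrackSet(tracks=tracks, frame_interval_s=dt), truth


# ---------------------------------------------------------------------------
# Puncta populations and the puromycin perturbation
# ---------------------------------------------------------------------------

@dataclass
class PunctaDistConfig:
    """Log-normal puncta-area population.

    Defaults reproduce the basal somatic distribution (median 4786.3 nm²,
    geometric SD 2.95).  ``unit_area_nm2`` is the area of one signal unit
    (the smallest detectable punctum); counts are ``ceil(area / unit)``.
    """

    n: int = 1000
    median_nm2: float = 4786.3
    gsd: float = 2.95
    unit_area_nm2: float = 500.0
    compartment: str = "soma"
    mean_intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.median_nm2 <= 0:
            raise ValueError("median_nm2 must be > 0")
        if self.gsd < 1:
            raise ValueError("geometric SD must be >= 1")


def simulate_puncta_population(cfg: SimConfig, dist_cfg: PunctaDistConfig) -> pd.DataFrame:
    """Sample a puncta population with log-normal areas.

    Returns a table with columns ``id, x, y, area_px, area_nm2,
    mean_intensity, signal_units, compartment``; the signal-unit area is
    stored in ``df.attrs['unit_area_nm2']`` and the pixel size in
    ``df.attrs['pixel_size_nm']``.
    """
    rng = cfg.rng()
    sig = math.log(dist_cfg.gsd)
    areas = dist_cfg.median_nm2 * np.exp(rng.normal(0.0, sig, size=dist_cfg.n))
    h, w = cfg.image_size
    x = rng.uniform(0, w, size=dist_cfg.n)
    y = rng.uniform(0, h, size=dist_cfg.n)
    units = np.ceil(areas / dist_cfg.unit_area_nm2).astype(int)
    units = np.maximum(units, 1)
    df = pd.DataFrame({
        "id": np.arange(dist_cfg.n),
        "x": x,
        "y": y,
        "area_px": areas / cfg.pixel_size_nm ** 2,
        "area_nm2": areas,
        "mean_intensity": np.full(dist_cfg.n, dist_cfg.mean_intensity),
        "signal_units": units,
        "compartment": dist_cfg.compartment,
    })
    df.attrs["unit_area_nm2"] = dist_cfg.unit_area_nm2
    df.attrs["pixel_size_nm"] = cfg.pixel_size_nm
    return df


@dataclass
class SplitConfig:
    """Puromycin-dissociation rule: every punctum holding more than
    ``threshold_units`` signal units is split into children of at most
    ``threshold_units`` units whose units sum exactly to the parent's."""

    threshold_units: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_units <= 0:
            raise ValueError("threshold_units must be > 0")


def apply_puromycin_dissociation(pop: pd.DataFrame, split_cfg: SplitConfig) -> pd.DataFrame:
    """Dissociate large puncta into small ones, conserving signal units.

    Models the puromycin response in which large puncta (polysome-scale
    assemblies) break apart while the total number of signal units stays
    constant.  Children inherit the parent's compartment and intensity and
    get positions jittered around the parent's.  Total signal units are
    conserved exactly; the punctum count never decreases.
    """
    rng = np.random.default_rng(split_cfg.seed)
    thr = split_cfg.threshold_units
    unit = pop.attrs.get("unit_area_nm2",
                         float(np.min(pop["area_nm2"] / pop["signal_units"]))
                         if len(pop) else 1.0)
    px = pop.attrs.get("pixel_size_nm", 108.0)
    rows = []
    for rec in pop.itertuples(index=False):
        if rec.signal_units <= thr:
            rows.append(rec._asdict() if hasattr(rec, "_asdict") else dict(rec._asdict()))
            continue
        remaining = int(rec.signal_units)
        while remaining > 0:
            child = int(rng.integers(1, thr + 1)) if remaining > thr else remaining
            remaining -= child
            area = child * unit
            rows.append({
                "id": -1,
                "x": rec.x + rng.normal(0, 2.0),
                "y": rec.y + rng.normal(0, 2.0),
                "area_px": area / px ** 2,
                "area_nm2": area,
                "mean_intensity": rec.mean_intensity,
                "signal_units": child,
                "compartment": rec.compartment,
            })
    out = pd.DataFrame(rows, columns=list(pop.columns))
    out["id"] = np.arange(len(out))
    out.attrs.update(pop.attrs)
    return out
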
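"""Synthetic inputs with known ground truth for every pipeline stage.

Purely phenomenological generators (no fluid-dynamics or neural-circuit
modelling) that emulate the data shapes of each pipeline stage:

* :func:`simulate_trace` — propagating peristaltic contraction waves on a
  2 cm gut segment sampled at 25 frames/s, with slow whole-segment drift and
  frame noise.
* :func:`render_frames` — a video stack of a bright horizontal tube whose
  local height follows a trace (round-trip fixture for edge tracking).
* :func:`simulate_cohort` — independently seeded labelled traces per group.
* :func:`simulate_count_matrix` — negative-binomial count matrices with
  stable housekeeping features, per-sample scaling and spiked up-regulated
  features, plus a ground-truth table.
* :func:`simulate_if_image` — fluorescence-like images with an exact
  positive-area fraction and countable, well-separated cell-like objects.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .motility import DiameterTrace

__all__ = [
    "WaveParams",
    "SpikeDesign",
    "simulate_trace",
    "render_frames",
    "simulate_cohort",
    "simulate_count_matrix",
    "simulate_if_image",
]

HOUSEKEEPING = ("Actb", "B2m", "Gapdh", "Rpl19")


@dataclass(frozen=True)
class WaveParams:
    """Parameters of the peristaltic wave generator.

    frequency : contractions per minute (0 disables the wave).
    amplitude : peak contraction depth, mm.
    velocity : propagation speed, mm/s; positive = aboral, negative =
        retrograde, ``math.inf`` = synchronous (zero lag between loci).
    baseline_diameter : resting diameter, mm.
    drift_amplitude / drift_period : slow sinusoidal whole-segment drift
        (mm / s); ``drift_slope`` adds a linear ramp (mm/s).
    noise_sd : frame noise scale, mm.  With ``noise_dist="normal"`` this is
        the Gaussian sd; with ``"uniform"`` it is the half-width of a bounded
        uniform distribution.
    duration, fps, n_loci, segment_length : acquisition geometry (defaults:
        25 frames/s, 30 loci over a 2 cm segment).
    duty : fraction of the period occupied by the contraction trough.
    dilatation_fraction : height of the dilatation lobe between contractions,
        as a fraction of ``amplitude``.
    """

    frequency: float = 40.0
    amplitude: float = 0.4
    velocity: float = 15.0
    baseline_diameter: float = 2.0
    drift_amplitude: float = 0.0
    drift_period: float = 120.0
    drift_slope: float = 0.0
    noise_sd: float = 0.02
    noise_dist: str = "normal"
    duration: float = 60.0
    fps: float = 25.0
    n_loci: int = 30
    segment_length: float = 2.0
    duty: float = 0.4
    dilatation_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frequency", "amplitude", "baseline_diameter",
                     "drift_amplitude", "drift_period", "noise_sd",
                     "duration", "fps", "segment_length"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.velocity == 0 or math.isnan(self.velocity):
            raise ValueError("velocity must be nonzero (use math.inf for synchronous)")
        if self.frequency > 0 and self.amplitude <= 0:
            raise ValueError("a nonzero frequency requires a positive amplitude")
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")
        if self.n_loci < 2:
            raise ValueError("need at least 2 loci")
        if not 0 < self.duty < 1:
            raise ValueError("duty must be in (0, 1)")
        if self.noise_dist not in ("normal", "uniform"):
            raise ValueError("noise_dist must be 'normal' or 'uniform'")

    @property
    def spacing_mm(self) -> float:
        return self.segment_length * 10.0 / self.n_loci

    @property
    def period_s(self) -> float:
        return 60.0 / self.frequency if self.frequency > 0 else math.inf


def _wave_shape(phase: np.ndarray, duty: float, amplitude: float,
                dilatation: float) -> np.ndarray:
    """Biphasic half-sine wave on phase in [0, 1).

    A contraction trough of depth ``amplitude`` occupies ``duty`` of the
    period; a dilatation lobe of height ``dilatation`` fills the rest, so the
    diameter swings above and below its slow average (dilatations positive,
    contractions negative after baseline removal) with a single
    zero-crossing pair per cycle.  Half-sine lobes give the crossings a
    non-zero slope — contractions start briskly, so the signal traverses the
    hysteresis band decisively instead of lingering inside it.
    """
    out = np.empty_like(phase)
    in_trough = phase < duty
    out[in_trough] = -amplitude * np.sin(np.pi * phase[in_trough] / duty)
    out[~in_trough] = dilatation * np.sin(np.pi * (phase[~in_trough] - duty) / (1 - duty))
    return out


def simulate_trace(params: WaveParams) -> DiameterTrace:
    """Simulate a diameter trace with propagating contraction waves.

    ``diameter(i, t) = baseline + drift(t) + noise - wave(t - lag_i)`` with
    ``lag_i = i * spacing / velocity`` (zero when velocity is infinite, i.e.
    synchronous).  The wave train is periodic in time, so for noise-free
    parameters each locus contains exactly ``frequency * duration / 60``
    contraction troughs when that product is an integer.
    """
    # independent substreams so toggling drift leaves the noise unchanged
    drift_rng, noise_rng = np.random.default_rng(params.seed).spawn(2)
    n_frames = int(round(params.duration * params.fps))
    t = np.arange(n_frames) / params.fps

    values = np.full((params.n_loci, n_frames), params.baseline_diameter)

    if params.frequency > 0 and params.amplitude > 0:
        period = params.period_s
        if math.isinf(params.velocity):
            lags = np.zeros(params.n_loci)
        else:
            lags = np.arange(params.n_loci) * params.spacing_mm / params.velocity
        phase = ((t[None, :] - lags[:, None]) / period) % 1.0
        values = values + _wave_shape(
            phase, params.duty, params.amplitude,
            params.dilatation_fraction * params.amplitude,
        )

    if params.drift_amplitude > 0 or params.drift_slope != 0:
        phi = drift_rng.uniform(0, 2 * np.pi)
        drift = (params.drift_amplitude
                 * np.sin(2 * np.pi * t / params.drift_period + phi)
                 + params.drift_slope * t)
        values = values + drift[None, :]

    if params.noise_sd > 0:
        if params.noise_dist == "normal":
            values = values + noise_rng.normal(0.0, params.noise_sd, values.shape)
        else:
            values = values + noise_rng.uniform(-params.noise_sd, params.noise_sd, values.shape)

    return DiameterTrace(values, fps=params.fps, segment_length_cm=params.segment_length)


def render_frames(
    trace: DiameterTrace,
    px_per_mm: float = 20.0,
    band_px: int = 4,
    margin_px: int = 8,
    height_px: int | None = None,
    foreground: float = 230.0,
    background: float = 20.0,
) -> np.ndarray:
    """Render a trace as a video stack of a bright horizontal tube.

    Each frame shows the tube on a dark background; its vertical extent at
    locus ``i`` equals ``trace[i, t] * px_per_mm`` (each locus occupies a
    ``band_px``-wide column band).  Sub-pixel coverage is anti-aliased so the
    edge-tracking round trip is accurate to <= 1 px.
    """
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    d_px = trace.values * px_per_mm
    max_d = float(d_px.max())
    height = int(height_px) if height_px is not None else int(np.ceil(max_d)) + 2 * margin_px
    if max_d >= height:
        raise ValueError(f"diameter {max_d:.1f} px exceeds frame height {height} px")
    width = trace.n_loci * band_px
    cy = height / 2.0
    y = np.arange(height) + 0.5

    # coverage of each pixel row by the tube, per locus and frame
    half = d_px / 2.0  # (loci, frames)
    dist = np.abs(y[None, None, :] - cy)  # (1, 1, H)
    cover = np.clip(half[:, :, None] - dist + 0.5, 0.0, 1.0)  # (loci, frames, H)
    intensity = background + (foreground - background) * cover
    # expand loci to column bands: (frames, H, W)
    stack = np.repeat(intensity.transpose(1, 2, 0), band_px, axis=2)
    return stack.astype(np.float32)


@dataclass(frozen=True)
class CohortMember:
    group: str
    trace: DiameterTrace


def simulate_cohort(
    wt: WaveParams,
    case: WaveParams,
    n_wt: int = 6,
    n_case: int = 7,
    seed: int = 0,
    labels: tuple[str, str] = ("WT", "case"),
    between_cv: float = 0.06,
) -> list[CohortMember]:
    """Simulate a two-group cohort of independently seeded traces.

    ``between_cv`` is the between-animal coefficient of variation applied
    (lognormally) to each animal's wave frequency and velocity around its
    group parameters; without it every animal in a group would produce
    identical endpoints and group statistics would degenerate.  The default
    0.06 mirrors the contraction-rate spread seen in real cohorts.  Set 0 for
    exact replicates.
    """
    import dataclasses as _dc

    if n_wt < 2 or n_case < 2:
        raise ValueError("need at least 2 animals per group")
    if between_cv < 0:
        raise ValueError("between_cv must be non-negative")
    children = np.random.SeedSequence(seed).spawn(n_wt + n_case)
    members = []
    sigma = math.sqrt(math.log(1 + between_cv**2)) if between_cv > 0 else 0.0
    for k, child in enumerate(children):
        group, base = (labels[0], wt) if k < n_wt else (labels[1], case)
        child_seed = int(child.generate_state(1)[0] % (2**31))
        animal = _dc.replace(base, seed=child_seed)
        if sigma > 0:
            jitter_rng = np.random.default_rng(child.spawn(1)[0])
            f_jit, v_jit = np.exp(jitter_rng.normal(-sigma**2 / 2, sigma, 2))
            velocity = animal.velocity if math.isinf(animal.velocity) else animal.velocity * v_jit
            animal = _dc.replace(animal, frequency=animal.frequency * f_jit,
                                 velocity=velocity)
        members.append(CohortMember(group, simulate_trace(animal)))
    return members


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeDesign:
    """Design of a spiked hybridisation-count experiment.

    ``n_features`` total features of which ``n_expressed`` (including the
    housekeeping set) are robustly expressed (high mean) and ``n_spiked`` of
    the expressed, non-housekeeping features are up-regulated in the case
    group by ``fold_change``.  Counts are negative binomial with
    ``dispersion`` (0 = Poisson); each sample carries a lognormal scale
    factor (library size) unless ``sample_scales`` is given.
    """

    n_features: int = 578
    n_expressed: int = 166
    n_spiked: int = 45
    fold_change: float = 2.0
    group_sizes: tuple[int, int] = (5, 6)  # (n_WT, n_case)
    housekeeping_names: Sequence[str] = HOUSEKEEPING
    dispersion: float = 0.05
    expressed_mean: float = 500.0
    background_mean: float = 10.0
    housekeeping_mean: float = 2000.0
    scale_sd: float = 0.15
    sample_scales: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n_hk = len(self.housekeeping_names)
        if not (self.n_spiked <= self.n_expressed - n_hk):
            raise ValueError("spiked features must fit among expressed non-housekeeping features")
        if self.n_expressed > self.n_features:
            raise ValueError("n_expressed must not exceed n_features")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if min(self.group_sizes) < 2:
            raise ValueError("need at least 2 samples per group")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_count_matrix(design: SpikeDesign):
    """Simulate a feature x sample count matrix plus its ground-truth table.

    Returns ``(CountMatrix, truth)`` where ``truth`` is a DataFrame indexed
    by feature with columns ``base_mean``, ``expressed``, ``spiked`` and
    ``fold_change``.  Housekeeping features share a common expected level
    across samples up to the sample scale factors and are never spiked.
    """
    from .omics import CountMatrix

    rng = np.random.default_rng(design.seed)
    hk = list(design.housekeeping_names)
    n_hk = len(hk)
    n_reg = design.n_features - n_hk
    features = hk + [f"miR-{k + 1:04d}" for k in range(n_reg)]

    n_wt, n_case = design.group_sizes
    samples = [f"WT_{k + 1}" for k in range(n_wt)] + [f"case_{k + 1}" for k in range(n_case)]
    groups = pd.Series(["WT"] * n_wt + ["case"] * n_case, index=samples, name="group")

    base = np.empty(design.n_features)
    base[:n_hk] = design.housekeeping_mean
    n_expr_reg = design.n_expressed - n_hk
    # lognormal spread around the expressed mean keeps a realistic dynamic range
    base[n_hk:n_hk + n_expr_reg] = design.expressed_mean * rng.lognormal(0.0, 0.5, n_expr_reg)
    base[n_hk + n_expr_reg:] = design.background_mean

    expressed = np.zeros(design.n_features, dtype=bool)
    expressed[:design.n_expressed] = True
    spiked = np.zeros(design.n_features, dtype=bool)
    spike_idx = n_hk + rng.choice(n_expr_reg, size=design.n_spiked, replace=False)
    spiked[spike_idx] = True

    if design.sample_scales is not None:
        scales = np.asarray(design.sample_scales, dtype=float)
        if scales.shape != (len(samples),):
            raise ValueError("sample_scales must have one entry per sample")
    else:
        scales = rng.lognormal(0.0, design.scale_sd, len(samples))

    mean = base[:, None] * scales[None, :]
    case_cols = np.arange(n_wt, n_wt + n_case)
    mean[np.ix_(spiked, case_cols)] *= design.fold_change
    counts = _nb_draw(rng, mean, design.dispersion).astype(float)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=features, columns=samples),
        groups=groups,
        housekeeping=hk,
        kind="miRNA_counts",
    )
    truth = pd.DataFrame({
        "base_mean": base,
        "expressed": expressed,
        "spiked": spiked,
        "fold_change": np.where(spiked, design.fold_change, 1.0),
    }, index=pd.Index(features, name="feature"))
    return matrix, truth


# ---------------------------------------------------------------------------
# Fluorescence-like images
# ---------------------------------------------------------------------------

def simulate_if_image(
    width: int = 256,
    height: int = 256,
    positive_fraction: float = 0.25,
    n_objects: int = 40,
    seed: int = 0,
    min_separation: int = 3,
    foreground: int = 220,
    background: int = 30,
):
    """Simulate a fluorescence image with exact positive area and objects.

    Places ``n_objects`` disjoint near-square blobs, jittered on a regular
    grid with at least ``min_separation`` px between them, whose total area is
    exactly ``round(positive_fraction * width * height)`` pixels.  Returns
    ``(image, truth)`` with ``truth = {"positive_fraction", "n_objects",
    "centroids"}``.  Raises ``ValueError`` for infeasible combinations.
    """
    if not 0 <= positive_fraction <= 1:
        raise ValueError("positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    image = np.full((height, width), background, dtype=np.uint8)
    target = int(round(positive_fraction * width * height))
    if target == 0:
        return image, {"positive_fraction": 0.0, "n_objects": 0, "centroids": []}
    if n_objects < 1:
        raise ValueError("positive_fraction > 0 requires n_objects >= 1")

    areas = np.full(n_objects, target // n_objects, dtype=int)
    areas[:target % n_objects] += 1
    if areas.min() < 1:
        raise ValueError("too many objects for the requested positive fraction")

    side = int(np.ceil(np.sqrt(areas.max())))
    box_h = side + 1  # room for the partial top row
    cell_w, cell_h = side + min_separation, box_h + min_separation
    n_cols, n_rows = width // cell_w, height // cell_h
    if n_cols * n_rows < n_objects:
        raise ValueError(
            f"cannot place {n_objects} objects of ~{areas.max()} px with "
            f"{min_separation} px separation in {width}x{height}"
        )
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    order = rng.permutation(len(cells))[:n_objects]

    centroids = []
    for k, ci in enumerate(order):
        r, c = cells[ci]
        a = int(areas[k])
        full_rows, rem = divmod(a, side)
        jy = rng.integers(0, max(1, cell_h - (full_rows + (rem > 0)) - min_separation))
        jx = rng.integers(0, max(1, cell_w - side - min_separation))
        y0, x0 = r * cell_h + jy, c * cell_w + jx
        image[y0:y0 + full_rows, x0:x0 + side] = foreground
        if rem:
            image[y0 + full_rows, x0:x0 + rem] = foreground
        ys, xs = np.nonzero(image[y0:y0 + full_rows + 1, x0:x0 + side] == foreground)
        centroids.append((y0 + ys.mean(), x0 + xs.mean()))

    truth = {
        "positive_fraction": target / (width * height),
        "n_objects": n_objects,
        "centroids": centroids,
    }
    return image, truth
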
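"""Spatiotemporal motility mapping of ex vivo gut-segment recordings.

The central object is a :class:`DiameterTrace`: gut diameter (mm) sampled at
``n_loci`` equally spaced positions along the segment (oral end at locus 0)
over time.  Traces are obtained either directly (TSV) or by tracking the upper
and lower tube edges in a video frame stack (:func:`track_edges`).  A slow
per-locus baseline (drift of the whole organ in the bath) is removed with a
moving median (:func:`baseline_correct`), yielding a signed amplitude map:
dilatations positive, contractions negative, relative to the local average
diameter.  Amplitudes can additionally be normalised to each locus' initial
diameter (:func:`normalize`) and rendered as a diverging-colour heatmap
(:func:`render_heatmap`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DiameterTrace",
    "SpatioTemporalMap",
    "track_edges",
    "baseline_correct",
    "normalize",
    "render_heatmap",
    "read_trace_tsv",
    "write_trace_tsv",
]


@dataclass(frozen=True)
class DiameterTrace:
    """Gut diameters in mm, shape (n_loci, n_frames), oral end at locus 0.

    Parameters
    ----------
    values
        Diameter matrix in mm; all entries must be positive and finite.
    fps
        Acquisition frame rate (frames/s).
    segment_length_cm
        Physical length of the mapped segment in cm (default 2 cm).
    """

    values: np.ndarray
    fps: float
    segment_length_cm: float = 2.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] < 2:
            raise ValueError("trace must be a loci x frames matrix with >= 2 loci")
        if not np.all(np.isfinite(values)):
            raise ValueError("trace contains non-finite diameters")
        if np.any(values <= 0):
            raise ValueError("diameters must be positive (mm)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if values.shape[1] < 2 * self.fps:
            raise ValueError("trace must cover at least 2 s of signal")
        if self.segment_length_cm <= 0:
            raise ValueError("segment length must be positive")

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def spacing_mm(self) -> float:
        """Distance between adjacent loci (section width), mm."""
        return self.segment_length_cm * 10.0 / self.n_loci

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class SpatioTemporalMap:
    """Baseline-corrected motility map.

    ``amplitude`` is the signed deviation from the slow baseline in mm
    (contractions negative, dilatations positive); ``baseline`` is the removed
    slow component, so ``amplitude + baseline`` reconstructs the input trace
    exactly.  ``normalized`` (fractions of the initial diameter) is filled in
    by :func:`normalize` and is ``None`` until then.
    """

    amplitude: np.ndarray
    baseline: np.ndarray
    fps: float
    segment_length_cm: float
    normalized: np.ndarray | None = None

    @property
    def n_loci(self) -> int:
        return self.amplitude.shape[0]

    @property
    def n_frames(self) -> int:
        return self.amplitude.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def spacing_mm(self) -> float:
        return self.segment_length_cm * 10.0 / self.n_loci

    def reconstruct(self) -> np.ndarray:
        """The input diameter matrix (mm): baseline + amplitude."""
        return self.amplitude + self.baseline


# ---------------------------------------------------------------------------
# Edge tracking
# ---------------------------------------------------------------------------

def _edge_extent(profile: np.ndarray, top: int, bottom: int) -> float:
    """Sub-pixel distance between the upper and lower tube borders.

    ``top``/``bottom`` are the outermost rows above the detection threshold.
    Each border is refined by interpolating where the (coverage-linear)
    intensity crosses the midpoint between the local background level and the
    tube plateau — the half-coverage point of the border pixel.
    """
    n = profile.size
    hi = float(profile[top:bottom + 1].max())
    lo = float(profile.min())
    mid = 0.5 * (lo + hi)

    def crossing(border: int, inward: int) -> float:
        # scan the short intensity ramp around the detected border row for
        # the mid-level crossing; `inward` is +1 for the upper border
        for j in range(border - 2 * inward, border + inward, inward):
            k = j + inward
            if not (0 <= j < n and 0 <= k < n):
                continue
            a, b = float(profile[j]), float(profile[k])
            if a < mid <= b:
                return (j + 0.5) + inward * (mid - a) / (b - a)
        return border + (0.0 if inward > 0 else 1.0)  # e.g. tube at image edge

    upper = crossing(top, +1)
    lower = crossing(bottom, -1)
    return lower - upper


def track_edges(
    frames: np.ndarray,
    n_loci: int,
    px_per_mm: float,
    fps: float,
    segment_length_cm: float = 2.0,
    max_flagged_fraction: float = 0.10,
) -> DiameterTrace:
    """Recover a diameter trace from a video stack of a horizontal gut tube.

    For each frame the image width is split into ``n_loci`` equal column
    bands.  Within a band, the mean intensity profile over rows is
    thresholded (Otsu, recomputed per frame so any monotone brightness
    rescaling leaves the result unchanged) and the outermost above-threshold
    rows define the upper and lower tube border; each border is refined to
    sub-pixel precision by linearly interpolating the threshold crossing,
    and the diameter is the border distance divided by ``px_per_mm``.

    Frames where no edge can be found at some locus (e.g. dropped/dark
    frames) are flagged and their diameters linearly interpolated in time
    from the neighbouring good frames.  If more than ``max_flagged_fraction``
    of frames are flagged, a ``ValueError`` is raised.
    """
    from skimage.filters import threshold_otsu

    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("expected a stack of >= 2 frames (t, y, x)")
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    n_frames, height, width = frames.shape
    band_edges = np.linspace(0, width, n_loci + 1).astype(int)

    diam_px = np.full((n_loci, n_frames), np.nan)
    flagged = np.zeros(n_frames, dtype=bool)
    for t in range(n_frames):
        frame = frames[t]
        if np.ptp(frame) == 0:
            flagged[t] = True
            continue
        thr = threshold_otsu(frame)
        ok = True
        for i in range(n_loci):
            profile = frame[:, band_edges[i]:band_edges[i + 1]].mean(axis=1)
            above = np.nonzero(profile > thr)[0]
            if above.size == 0:
                ok = False
                break
            diam_px[i, t] = _edge_extent(profile, above[0], above[-1])
        if not ok:
            flagged[t] = True
            diam_px[:, t] = np.nan

    n_flagged = int(flagged.sum())
    if n_flagged > max_flagged_fraction * n_frames:
        raise ValueError(
            f"{n_flagged}/{n_frames} frames had undetectable edges "
            f"(> {max_flagged_fraction:.0%} allowed)"
        )
    if n_flagged:
        good = np.nonzero(~flagged)[0]
        if good.size == 0:
            raise ValueError("no frame with detectable edges")
        bad = np.nonzero(flagged)[0]
        for i in range(n_loci):
            diam_px[i, bad] = np.interp(bad, good, diam_px[i, good])

    return DiameterTrace(diam_px / px_per_mm, fps=fps, segment_length_cm=segment_length_cm)


# ---------------------------------------------------------------------------
# Baseline correction and normalisation
# ---------------------------------------------------------------------------

def baseline_correct(trace: DiameterTrace, window_s: float) -> SpatioTemporalMap:
    """Remove the slow per-locus baseline with a centred moving median.

    ``window_s`` must be clearly longer than the longest expected contraction
    cycle so the median tracks drift, not the waves themselves.  The median
    (rather than a moving mean) is robust to the asymmetric contraction
    troughs.  Each locus is processed independently.
    """
    if window_s <= 2.0 / trace.fps:
        raise ValueError("baseline window must exceed two frame periods")
    w = int(round(window_s * trace.fps))
    w = max(3, w | 1)  # odd, centred
    df = pd.DataFrame(trace.values.T)
    baseline = df.rolling(w, center=True, min_periods=1).median().to_numpy().T
    amplitude = trace.values - baseline
    return SpatioTemporalMap(
        amplitude=amplitude,
        baseline=baseline,
        fps=trace.fps,
        segment_length_cm=trace.segment_length_cm,
    )


def normalize(stmap: SpatioTemporalMap, initial_window_s: float = 1.0) -> SpatioTemporalMap:
    """Express amplitudes as fractions of each locus' initial diameter.

    The initial diameter is the mean reconstructed diameter over the first
    ``initial_window_s`` seconds (averaging damps frame noise).  The sign
    convention (contraction negative) is preserved.
    """
    k = max(1, int(round(initial_window_s * stmap.fps)))
    trace = stmap.reconstruct()
    initial = trace[:, :k].mean(axis=1)
    if np.any(initial <= 0):
        bad = int(np.argmax(initial <= 0))
        raise ValueError(f"non-positive initial diameter at locus {bad}")
    return dataclasses.replace(stmap, normalized=stmap.amplitude / initial[:, None])


def render_heatmap(
    stmap: SpatioTemporalMap,
    out_path: str | Path,
    vlim: float | None = None,
    use_normalized: bool = False,
) -> Path:
    """Render the map as a PNG heatmap (time on x, oral->aboral on y).

    A symmetric diverging colour scale centred at zero amplitude is used;
    colour limits default to the maximum absolute amplitude.  With explicit
    ``vlim`` the rendering is deterministic and reproducible.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = stmap.normalized if use_normalized else stmap.amplitude
    if data is None:
        raise ValueError("normalized map requested but not computed; call normalize()")
    if data.size == 0:
        raise ValueError("empty map")
    vmax = float(vlim) if vlim is not None else float(np.max(np.abs(data)))
    if vmax == 0:
        vmax = 1.0
    fig, ax = plt.subplots(figsize=(8, 3), dpi=150)
    im = ax.imshow(
        data,
        aspect="auto",
        cmap="RdBu",
        vmin=-vmax,
        vmax=vmax,
        extent=(0, stmap.duration_s, stmap.segment_length_cm * 10, 0),
        interpolation="nearest",
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("position, oral → aboral (mm)")
    unit = "fraction of initial diameter" if use_normalized else "amplitude (mm)"
    fig.colorbar(im, ax=ax, label=unit)
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


# ---------------------------------------------------------------------------
# Trace I/O: TSV (first column = locus index) + JSON sidecar with calibration
# ---------------------------------------------------------------------------

def write_trace_tsv(trace: DiameterTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(trace.values)
    df.insert(0, "locus", np.arange(trace.n_loci))
    df.to_csv(path, sep="\t", index=False, header=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "fps": trace.fps,
        "segment_length_cm": trace.segment_length_cm,
        "spacing_mm": trace.spacing_mm,
        "n_loci": trace.n_loci,
    }))
    return path


def read_trace_tsv(path: str | Path, fps: float | None = None,
                   segment_length_cm: float | None = None) -> DiameterTrace:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    fps = fps if fps is not None else meta.get("fps")
    segment_length_cm = (segment_length_cm if segment_length_cm is not None
                         else meta.get("segment_length_cm", 2.0))
    if fps is None:
        raise ValueError("fps not given and no sidecar JSON found")
    raw = pd.read_csv(path, sep="\t", header=None)
    order = np.argsort(raw.iloc[:, 0].to_numpy())
    values = raw.iloc[order, 1:].to_numpy(dtype=float)
    return DiameterTrace(values, fps=float(fps), segment_length_cm=float(segment_length_cm))
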
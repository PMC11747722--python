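"""Waveform -> validated 0.1 Hz trends -> reactivity indices -> period summaries.

Processing chain:

1. :func:`coarse_grain` — 10-s non-overlapping block averages per channel, with
   a validity mask (a block needs >= 50% valid raw samples).
2. :func:`compute_amp` — intracranial pulse pressure amplitude per block,
   2x the spectral magnitude of ICP at the fundamental cardiac frequency
   (peak-to-peak convention), or a per-beat peak-to-peak median.
3. :func:`reject_artifacts` — threshold rules on block values: ICP outside
   [-10, 60] mmHg rejected; CPP = ABP - ICP outside [0, 150] mmHg rejects the
   block for both ICP and CPP.
4. :func:`moving_correlation` — Pearson r over a 5-min window of 30 blocks,
   updated every minute; Fisher z = atanh(r) with |r| clamped to 0.99.
   PRx correlates ABP with ICP, RAP correlates AMP with ICP.
5. :func:`summarize_periods` — per-period means over valid entries; PRx/RAP
   averaged on the z scale and reported both ways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import WaveformRecording, design_from_recording

BLOCK_S = 10.0
WINDOW_BLOCKS = 30     # 5-min window of 10-s averages
UPDATE_BLOCKS = 6      # updated every minute
MIN_VALID_PAIRS = 24
FISHER_CLAMP = 0.99
ICP_LIMITS = (-10.0, 60.0)
CPP_LIMITS = (0.0, 150.0)
CARDIAC_BAND = (0.5, 5.0)


@dataclass
class TrendSeries:
    """0.1 Hz coarse-grained trends: block end-times, values and validity."""

    time: np.ndarray                 # block end times, seconds
    data: pd.DataFrame               # one column per channel
    valid: pd.DataFrame              # boolean, same shape as data
    block_s: float = BLOCK_S

    def __post_init__(self) -> None:
        if len(self.time) != len(self.data) or len(self.data) != len(self.valid):
            raise ValueError("time, data and valid must align")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def masked(self, channel: str) -> np.ndarray:
        """Channel values with invalid blocks as NaN."""
        x = self.data[channel].to_numpy(dtype=float).copy()
        x[~self.valid[channel].to_numpy()] = np.nan
        return x

    def copy(self) -> "TrendSeries":
        return TrendSeries(self.time.copy(), self.data.copy(),
                           self.valid.copy(), self.block_s)


# ---------------------------------------------------------------------------


def coarse_grain(rec: WaveformRecording, block_s: float = BLOCK_S,
                 raw_limits: dict[str, tuple[float, float]] | None = None,
                 min_raw_fraction: float = 0.5) -> TrendSeries:
    """Downsample to 0.1 Hz by non-overlapping block averages.

    Raw samples that are non-finite (or outside ``raw_limits[channel]`` when
    given) are excluded from the mean; a block with fewer than
    ``min_raw_fraction`` valid samples is marked invalid.  A trailing partial
    block is dropped.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    spb_f = rec.sampling_rate * block_s
    spb = int(round(spb_f))
    if abs(spb_f - spb) > 1e-6 or spb < 1:
        raise ValueError("sampling_rate x block_s must be an integer sample count")
    n_blocks = rec.n_samples // spb
    if n_blocks == 0:
        raise ValueError("recording shorter than one block")
    time = (np.arange(n_blocks) + 1) * block_s
    data, valid = {}, {}
    for name, x in rec.channels.items():
        xb = x[: n_blocks * spb].reshape(n_blocks, spb)
        ok = np.isfinite(xb)
        if raw_limits and name in raw_limits:
            lo, hi = raw_limits[name]
            ok &= (xb >= lo) & (xb <= hi)
        cnt = ok.sum(axis=1)
        s = np.where(ok, xb, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
        data[name] = mean
        valid[name] = cnt >= min_raw_fraction * spb
    return TrendSeries(time=time, data=pd.DataFrame(data),
                       valid=pd.DataFrame(valid), block_s=block_s)


def reject_artifacts(trend: TrendSeries,
                     icp_limits: tuple[float, float] = ICP_LIMITS,
                     cpp_limits: tuple[float, float] = CPP_LIMITS) -> TrendSeries:
    """Apply threshold rejection on block values and derive the CPP channel.

    ICP blocks outside ``icp_limits`` are invalidated.  CPP = ABP - ICP; blocks
    with CPP outside ``cpp_limits`` invalidate both ICP and CPP.  No invalid
    block is ever revalidated.
    """
    for ch in ("ICP", "ABP"):
        if ch not in trend.data.columns:
            raise KeyError(f"required channel {ch!r} missing")
    out = trend.copy()
    icp = out.data["ICP"].to_numpy(dtype=float)
    abp = out.data["ABP"].to_numpy(dtype=float)
    icp_ok = out.valid["ICP"].to_numpy().copy()
    abp_ok = out.valid["ABP"].to_numpy()

    with np.errstate(invalid="ignore"):
        in_range = (icp >= icp_limits[0]) & (icp <= icp_limits[1])
    icp_ok &= np.where(np.isfinite(icp), in_range, False)

    cpp = abp - icp
    cpp_ok = icp_ok & abp_ok
    with np.errstate(invalid="ignore"):
        cpp_in = (cpp >= cpp_limits[0]) & (cpp <= cpp_limits[1])
    cpp_in = np.where(np.isfinite(cpp), cpp_in, False)
    icp_ok &= ~(cpp_ok & ~cpp_in)   # out-of-range CPP rejects the ICP block too
    cpp_ok &= cpp_in

    out.data["CPP"] = cpp
    out.valid["ICP"] = icp_ok
    out.valid["CPP"] = cpp_ok
    return out


# ---------------------------------------------------------------------------
# pulse amplitude


def detect_cardiac_frequency(rec: WaveformRecording,
                             channel: str = "ABP",
                             band: tuple[float, float] = CARDIAC_BAND) -> float:
    """Fundamental cardiac frequency from the strongest spectral peak of the
    pulse channel within the physiological band."""
    x = rec.channels[channel]
    n = min(len(x), int(rec.sampling_rate * 600))  # first 10 min suffice
    x = x[:n] - np.mean(x[:n])
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.sampling_rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any() or not np.any(spec[sel] > 0):
        raise ValueError("no cardiac component detectable in band")
    f = float(freqs[sel][np.argmax(spec[sel])])
    if not band[0] <= f <= band[1]:
        raise ValueError(f"cardiac frequency {f:.2f} Hz outside {band}")
    return f


def compute_amp(rec: WaveformRecording, cardiac_hz: float | None = None,
                block_s: float = BLOCK_S, method: str = "spectral") -> np.ndarray:
    """ICP pulse pressure amplitude per 10-s block (peak-to-peak convention).

    ``spectral``: 2x the magnitude of the ICP component at the fundamental
    cardiac frequency, estimated by complex projection within each block (a
    sinusoid of amplitude A yields AMP = 2A).  ``beat``: median per-beat
    peak-to-peak excursion within the block.
    """
    if "ICP" not in rec.channels:
        raise KeyError("ICP channel required")
    f = detect_cardiac_frequency(rec) if cardiac_hz is None else float(cardiac_hz)
    if not CARDIAC_BAND[0] <= f <= CARDIAC_BAND[1]:
        raise ValueError(f"cardiac frequency {f} Hz outside {CARDIAC_BAND}")
    spb = int(round(rec.sampling_rate * block_s))
    n_blocks = rec.n_samples // spb
    x = rec.channels["ICP"][: n_blocks * spb].reshape(n_blocks, spb)
    if method == "spectral":
        # joint least squares per block onto {1, t, cos(2pi f t), sin(2pi f t)}:
        # the linear term keeps slow drift out of the cardiac component
        tt = np.arange(spb) / rec.sampling_rate
        g = np.column_stack([np.ones(spb), tt - tt.mean(),
                             np.cos(2 * np.pi * f * tt),
                             np.sin(2 * np.pi * f * tt)])
        coef, *_ = np.linalg.lstsq(g, x.T, rcond=None)
        amplitude = np.hypot(coef[2], coef[3])
        return 2.0 * amplitude           # peak-to-peak convention
    if method == "beat":
        x = x - x.mean(axis=1, keepdims=True)
        beat = int(round(rec.sampling_rate / f))
        nb = spb // beat
        if nb < 1:
            raise ValueError("block shorter than one cardiac cycle")
        seg = x[:, : nb * beat].reshape(n_blocks, nb, beat)
        return np.median(seg.max(axis=2) - seg.min(axis=2), axis=1)
    raise ValueError(f"unknown AMP method {method!r}")


def add_amp(trend: TrendSeries, rec: WaveformRecording,
            cardiac_hz: float | None = None, method: str = "spectral") -> TrendSeries:
    """Insert the AMP channel into a trend series (validity follows ICP)."""
    amp = compute_amp(rec, cardiac_hz=cardiac_hz, block_s=trend.block_s,
                      method=method)
    out = trend.copy()
    out.data["AMP"] = amp[: len(out.data)]
    out.valid["AMP"] = out.valid["ICP"].to_numpy()[: len(out.data)]
    return out


# ---------------------------------------------------------------------------
# moving-window correlation indices


def moving_correlation(trend: TrendSeries, x_channel: str, y_channel: str,
                       window_blocks: int = WINDOW_BLOCKS,
                       update_blocks: int = UPDATE_BLOCKS,
                       min_valid: int = MIN_VALID_PAIRS) -> pd.DataFrame:
    """Pearson r between two trend channels over a trailing window.

    One row per update instant (every ``update_blocks`` blocks, first emitted
    once a full window is available).  A window is invalid when fewer than
    ``min_valid`` pairs are jointly valid or either side is constant.
    Columns: time, r, z (Fisher, clamped), n, valid.
    """
    for ch in (x_channel, y_channel):
        if ch not in trend.data.columns:
            raise KeyError(f"channel {ch!r} missing from trend series")
    x = trend.data[x_channel].to_numpy(dtype=float)
    y = trend.data[y_channel].to_numpy(dtype=float)
    ok = (trend.valid[x_channel] & trend.valid[y_channel]).to_numpy()
    ok &= np.isfinite(x) & np.isfinite(y)

    rows = []
    for end in range(window_blocks, len(x) + 1, update_blocks):
        sl = slice(end - window_blocks, end)
        m = ok[sl]
        n = int(m.sum())
        t = float(trend.time[end - 1])
        if n < min_valid:
            rows.append((t, np.nan, np.nan, n, False))
            continue
        xs, ys = x[sl][m], y[sl][m]
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            rows.append((t, np.nan, np.nan, n, False))
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        r = float(np.clip(r, -1.0, 1.0))
        z = float(np.arctanh(np.clip(r, -FISHER_CLAMP, FISHER_CLAMP)))
        rows.append((t, r, z, n, True))
    return pd.DataFrame(rows, columns=["time", "r", "z", "n", "valid"])


def compute_prx(trend: TrendSeries, **kwargs) -> pd.DataFrame:
    """Pressure reactivity index: moving correlation of ABP and ICP blocks."""
    return moving_correlation(trend, "ABP", "ICP", **kwargs)


def compute_rap(trend: TrendSeries, **kwargs) -> pd.DataFrame:
    """Compensatory reserve index: moving correlation of AMP and ICP blocks."""
    return moving_correlation(trend, "AMP", "ICP", **kwargs)


# ---------------------------------------------------------------------------
# period summaries


def _window_span_s(window_blocks: int = WINDOW_BLOCKS,
                   block_s: float = BLOCK_S) -> float:
    return window_blocks * block_s


def summarize_periods(trend: TrendSeries, indices: dict[str, pd.DataFrame],
                      design: pd.DataFrame,
                      window_blocks: int = WINDOW_BLOCKS) -> pd.DataFrame:
    """Per-period means of trends and indices.

    Trend blocks belong to a period when their end time falls in
    ``(start, end]``.  Index entries are used only when their whole window lies
    inside the period, so estimates never straddle an intervention change.
    PRx/RAP are averaged on the Fisher-z scale; ``prx = tanh(mean z)`` is
    reported alongside.  Change-from-baseline columns are taken against the
    first PEEP-baseline period of the same position block.
    """
    span = _window_span_s(window_blocks, trend.block_s)
    rows = []
    for d in design.itertuples():
        row = dict(animal=d.animal, block=int(d.block),
                   period_order=int(getattr(d, "period_order", d.block)),
                   position=d.position, peep=float(d.peep), label=d.label,
                   period_id=d.period_id,
                   sequence=getattr(d, "sequence", None),
                   start_s=float(d.start_s), end_s=float(d.end_s))
        sel = (trend.time > d.start_s) & (trend.time <= d.end_s)
        n_valid_any = 0
        for ch in trend.channels:
            vals = trend.masked(ch)[sel]
            good = np.isfinite(vals)
            n_valid_any = max(n_valid_any, int(good.sum()))
            row[ch.lower()] = float(np.mean(vals[good])) if good.any() else np.nan
        for name, idx in indices.items():
            inside = (idx["time"] - span >= d.start_s - 1e-9) & \
                     (idx["time"] <= d.end_s + 1e-9) & idx["valid"]
            z = idx.loc[inside, "z"]
            row[f"{name}_z"] = float(z.mean()) if len(z) else np.nan
            row[name] = float(np.tanh(z.mean())) if len(z) else np.nan
            row[f"{name}_n"] = int(len(z))
        row["n_valid_blocks"] = n_valid_any
        row["excluded"] = n_valid_any == 0
        rows.append(row)
    out = pd.DataFrame(rows)

    from .synth import add_delta_columns
    delta_cols = tuple(c for c in ("icp", "prx_z", "rap_z", "cpp", "amp")
                       if c in out.columns)
    return add_delta_columns(out, columns=delta_cols)


def process_recording(rec: WaveformRecording,
                      design: pd.DataFrame | None = None,
                      cardiac_hz: float | None = None,
                      amp_method: str = "spectral",
                      artifact_level: str = "block",
                      icp_limits: tuple[float, float] = ICP_LIMITS,
                      cpp_limits: tuple[float, float] = CPP_LIMITS,
                      min_valid_pairs: int = MIN_VALID_PAIRS,
                      min_raw_fraction: float = 0.5,
                      ) -> tuple[TrendSeries, dict[str, pd.DataFrame], pd.DataFrame]:
    """Full trend chain for one recording.

    Returns (trend series with AMP and CPP, {'prx':..., 'rap':...}, period
    summary table).  With ``artifact_level='raw'`` the ICP thresholds are also
    applied to raw samples before averaging.
    """
    raw_limits = {"ICP": icp_limits} if artifact_level == "raw" else None
    trend = coarse_grain(rec, raw_limits=raw_limits,
                         min_raw_fraction=min_raw_fraction)
    trend = add_amp(trend, rec, cardiac_hz=cardiac_hz, method=amp_method)
    trend = reject_artifacts(trend, icp_limits=icp_limits, cpp_limits=cpp_limits)
    indices = {
        "prx": compute_prx(trend, min_valid=min_valid_pairs),
        "rap": compute_rap(trend, min_valid=min_valid_pairs),
    }
    if design is None:
        design = design_from_recording(rec)
    summary = summarize_periods(trend, indices, design)
    return trend, indices, summary
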
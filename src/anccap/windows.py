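"""Sliding-window divergence vs. capture efficiency.

The central readout of an ancestral-capture experiment: slide fixed
windows (60 bp, step 30 bp by default) along the bait-source/target
alignment, record per-window identity and per-window mean depth in the
capture and shotgun libraries, and summarise — per divergence bin — the
proportion of windows and the proportion of sequencing depth each library
places there.  A shotgun library is the neutral baseline (depth tracks
window abundance); capture depth shifts toward low-divergence windows,
and the capture/shotgun depth ratio as a function of identity is fit with
a logistic retention curve to recover the underlying capture model.

Also provides a banded global affine-gap aligner for whole-mitogenome
identity and a tricube local-linear smoother for trendlines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from anccap.seqio import AlignedRead
from anccap.simgen import CaptureModel

log = logging.getLogger(__name__)

NEG_INF = -1e30


@dataclass
class WindowParams:
    """Window geometry and binning for the divergence-response analysis.

    The 2-15 kb default region excludes the rRNAs and the control region,
    where indel differences between a divergent bait source and its target
    make ungapped window identity meaningless.
    """

    window: int = 60
    step: int = 30
    region: tuple[int, int] = (2000, 15000)
    bin_width: float = 0.02

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if not 0.0 < self.bin_width <= 0.1:
            raise ValueError("bin_width must be in (0, 0.1]")
        if self.region[0] >= self.region[1]:
            raise ValueError("empty region")


@dataclass
class WindowStat:
    """One window: identity to the bait source and per-library mean depth."""

    start: int
    end: int
    identity: float
    depth_capture: float = float("nan")
    depth_shotgun: float = float("nan")
    has_gap: bool = False

    @property
    def divergence(self) -> float:
        return 1.0 - self.identity


# ---------------------------------------------------------------------------
# banded global alignment


@dataclass
class PairwiseAlignment:
    """Global alignment rows (with ``-`` gaps), score and identity.

    Identity counts matched columns over columns where both rows carry an
    unambiguous base, excluding terminal gap runs.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float


def _identity_from_rows(ra: str, rb: str) -> float:
    a = np.array(list(ra))
    b = np.array(list(rb))
    both = (a != "-") & (b != "-")
    idx = np.nonzero(both)[0]
    if idx.size == 0:
        return 0.0
    lo, hi = idx[0], idx[-1] + 1  # trim terminal gap runs
    a, b = a[lo:hi], b[lo:hi]
    comparable = np.isin(a, list("ACGT")) & np.isin(b, list("ACGT"))
    if not comparable.any():
        return 0.0
    return float(((a == b) & comparable).sum() / comparable.sum())


def align_banded(
    seq_a: str,
    seq_b: str,
    band_width: int = 200,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment within a diagonal band.

    A gap of length g costs ``gap_open + g * gap_extend``.  Collinear
    mitogenomes stay within a narrow band; if the band constrains the
    optimum — detected when the optimal path touches the band boundary or
    when doubling the band improves the score — the band is doubled with a
    warning and the alignment recomputed, so the returned alignment is
    band-unconstrained in practice.  Sequences whose length difference
    reaches the band are rejected.
    """
    if abs(len(seq_a) - len(seq_b)) >= band_width:
        raise ValueError(
            f"length difference {abs(len(seq_a) - len(seq_b))} exceeds band width {band_width}"
        )
    band = band_width
    result, touched = _align_banded_once(seq_a, seq_b, band, match, mismatch, gap_open, gap_extend)
    while band < 4 * max(len(seq_a), len(seq_b)):
        wider, w_touched = _align_banded_once(
            seq_a, seq_b, band * 2, match, mismatch, gap_open, gap_extend
        )
        if not touched and wider.score <= result.score + 1e-9:
            return result
        warnings.warn(f"band {band} constrains the alignment; widening to {band * 2}")
        band *= 2
        result, touched = wider, w_touched
    return result


def _align_banded_once(seq_a, seq_b, band, match, mismatch, gap_open, gap_extend):
    n, m = len(seq_a), len(seq_b)
    W = 2 * band + 1
    a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)

    # cell (i, j) lives at column d = j - i + band of row i
    ds = np.arange(W)
    go_ge = gap_open + gap_extend

    M_prev = np.full(W, NEG_INF)
    X_prev = np.full(W, NEG_INF)
    Y_prev = np.full(W, NEG_INF)
    # row 0: j = d - band
    j0 = ds - band
    valid0 = (j0 >= 0) & (j0 <= m)
    M_prev[band] = 0.0
    with np.errstate(invalid="ignore"):
        Y_prev[valid0 & (j0 > 0)] = gap_open + gap_extend * j0[valid0 & (j0 > 0)]

    # traceback pointers: 0=M, 1=X (gap in B, vertical), 2=Y (gap in A, horizontal)
    ptr_M = np.zeros((n + 1, W), dtype=np.int8)
    ptr_X = np.zeros((n + 1, W), dtype=np.int8)
    ptr_Y = np.zeros((n + 1, W), dtype=np.int8)

    ge_d = gap_extend * ds
    for i in range(1, n + 1):
        j = i + ds - band
        valid = (j >= 1) & (j <= m)
        jc = np.clip(j - 1, 0, m - 1)
        sub = np.where(a[i - 1] == b[jc], match, mismatch)

        # M: diagonal from (i-1, j-1) -> same d in previous row
        stack = np.vstack((M_prev, X_prev, Y_prev))
        ptr_M[i] = stack.argmax(axis=0)
        M = sub + stack.max(axis=0)
        M[~valid] = NEG_INF

        # X: vertical from (i-1, j) -> d+1 in previous row
        Mp = np.full(W, NEG_INF)
        Xp = np.full(W, NEG_INF)
        Mp[:-1] = M_prev[1:]
        Xp[:-1] = X_prev[1:]
        open_x = Mp + go_ge
        ext_x = Xp + gap_extend
        ptr_X[i] = np.where(open_x >= ext_x, 0, 1)
        X = np.maximum(open_x, ext_x)
        X[j > m] = NEG_INF
        X[j < 0] = NEG_INF

        # Y: horizontal within the row; Y[d] = max_{k<d}(M[k] + go + (d-k)*ge)
        # and Y may also extend from Y itself, which the running max covers
        # because an optimal horizontal run always starts from M.
        cand = M - ge_d
        run = np.full(W, NEG_INF)
        if W > 1:
            run[1:] = np.maximum.accumulate(cand[:-1])
        Y = run + ge_d + gap_open
        Y[~valid] = NEG_INF
        # branch pointers recoverable because Y[d-1] is known
        prevY = np.full(W, NEG_INF)
        prevY[1:] = Y[:-1]
        prevM = np.full(W, NEG_INF)
        prevM[1:] = M[:-1]
        ptr_Y[i] = np.where(prevM + go_ge >= prevY + gap_extend, 0, 2)

        M_prev, X_prev, Y_prev = M, X, Y

    d_end = m - n + band
    finals = np.array([M_prev[d_end], X_prev[d_end], Y_prev[d_end]])
    state = int(finals.argmax())
    score = float(finals.max())

    # second pass to regenerate rows for traceback would double work; instead
    # rebuild the path from stored pointers alone.
    ra: list[str] = []
    rb: list[str] = []
    i, d = n, d_end
    touched = False
    while i > 0 or d != band:
        if d <= 0 or d >= W - 1:
            touched = True
        j = i + d - band
        if i == 0:
            # only horizontal moves remain
            ra.append("-")
            rb.append(seq_b[j - 1])
            d -= 1
            continue
        if j == 0:
            ra.append(seq_a[i - 1])
            rb.append("-")
            i -= 1
            d += 1
            continue
        if state == 0:
            ra.append(seq_a[i - 1])
            rb.append(seq_b[j - 1])
            state = int(ptr_M[i, d])
            i -= 1  # same d
        elif state == 1:
            ra.append(seq_a[i - 1])
            rb.append("-")
            state = 0 if ptr_X[i, d] == 0 else 1
            i -= 1
            d += 1
        else:
            ra.append("-")
            rb.append(seq_b[j - 1])
            state = 0 if ptr_Y[i, d] == 0 else 2
            d -= 1
    row_a = "".join(reversed(ra))
    row_b = "".join(reversed(rb))
    aln = PairwiseAlignment(row_a, row_b, score, _identity_from_rows(row_a, row_b))
    return aln, touched


# ---------------------------------------------------------------------------
# windows


def window_identity(
    row_a: str,
    row_b: str,
    params: WindowParams,
) -> list[WindowStat]:
    """Sliding-window identity over two aligned, equal-length rows.

    Windows are anchored at the region start and advance by ``step`` while
    ``start + window <= region end`` (windows straddling the region
    boundary are excluded).  Identity counts matches over columns where
    both rows are unambiguous bases; windows containing any gap or N are
    gap-flagged.  Coordinates are alignment columns (equal to sequence
    positions for gap-free rows).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must be equal length (align first)")
    lo, hi = params.region
    if hi > len(row_a):
        raise ValueError(f"region {params.region} outside alignment of length {len(row_a)}")
    if params.window > hi - lo:
        raise ValueError("window longer than region")
    a = np.frombuffer(row_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(row_b.encode("ascii"), dtype=np.uint8)
    good_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    ok_a = np.isin(a, good_codes)
    ok_b = np.isin(b, good_codes)
    both = ok_a & ok_b
    eq = (a == b) & both
    out: list[WindowStat] = []
    for start in range(lo, hi - params.window + 1, params.step):
        end = start + params.window
        n_comp = int(both[start:end].sum())
        n_match = int(eq[start:end].sum())
        has_gap = n_comp < params.window
        identity = n_match / n_comp if n_comp else float("nan")
        out.append(WindowStat(start=start, end=end, identity=identity, has_gap=has_gap))
    return out


def depth_vector(reads: Sequence[AlignedRead], ref_length: int) -> np.ndarray:
    """Per-position read coverage."""
    d = np.zeros(ref_length, dtype=np.int64)
    for r in reads:
        if r.end > ref_length:
            raise ValueError(f"read {r.name} outside reference")
        d[r.start : r.end] += 1
    return d


def window_depth(
    reads: Sequence[AlignedRead],
    wins: Sequence[WindowStat],
    ref_length: int,
    which: str = "capture",
) -> list[WindowStat]:
    """Fill each window's mean per-base depth from a read set (in place).

    ``which`` selects the field to fill ("capture" or "shotgun").
    """
    if which not in ("capture", "shotgun"):
        raise ValueError("which must be 'capture' or 'shotgun'")
    d = depth_vector(reads, ref_length)
    for w in wins:
        if w.end > ref_length:
            raise ValueError(f"window [{w.start},{w.end}) outside reference")
        mean = float(d[w.start : w.end].mean())
        if which == "capture":
            w.depth_capture = mean
        else:
            w.depth_shotgun = mean
    return list(wins)


def divergence_response(wins: Sequence[WindowStat], params: WindowParams) -> pd.DataFrame:
    """Per-divergence-bin summary of window abundance and depth shares.

    Gap-flagged windows are excluded.  For each occupied bin the table
    reports the proportion of windows, the proportion of total capture
    depth, the proportion of total shotgun depth, and the
    capture/shotgun ratio of those proportions (NaN where the shotgun
    share is zero).  Window proportions sum to 1; each depth-share column
    sums to 1 over the occupied bins.
    """
    clean = [w for w in wins if not w.has_gap]
    if not clean:
        raise ValueError("all windows are gap-flagged")
    div = np.array([w.divergence for w in clean])
    dcap = np.array([w.depth_capture for w in clean])
    dsho = np.array([w.depth_shotgun for w in clean])
    bins = np.floor(div / params.bin_width).astype(int)
    # windows at exactly the upper edge of the last bin stay in it
    rows = []
    tot_cap = np.nansum(dcap)
    tot_sho = np.nansum(dsho)
    for b in sorted(set(bins)):
        sel = bins == b
        n_win = int(sel.sum())
        if n_win < 5:
            log.warning("divergence bin [%.2f, %.2f) has only %d windows",
                        b * params.bin_width, (b + 1) * params.bin_width, n_win)
        prop_cap = float(np.nansum(dcap[sel]) / tot_cap) if tot_cap > 0 else float("nan")
        prop_sho = float(np.nansum(dsho[sel]) / tot_sho) if tot_sho > 0 else float("nan")
        rows.append(
            {
                "bin_low": b * params.bin_width,
                "bin_high": (b + 1) * params.bin_width,
                "n_windows": n_win,
                "prop_windows": n_win / len(clean),
                "prop_capture": prop_cap,
                "prop_shotgun": prop_sho,
                "ratio": prop_cap / prop_sho if prop_sho and prop_sho > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trendline


def loess_trend(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.5,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tricube-weighted local linear regression evaluated on a grid.

    At each grid point the nearest ``ceil(span * n)`` observations get
    tricube weights ``(1 - (d/h)^3)^3`` (h = the bandwidth, the distance
    to the furthest included point) and a weighted straight line is fit;
    the fitted value at the grid point is returned.  Collinear input is
    reproduced exactly, since a local line fits a global line everywhere.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 points")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    k = max(3, int(np.ceil(span * n)))
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, dtype=float)
    fitted = np.empty_like(grid)
    for gi, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            fitted[gi] = y[d == 0].mean()
            continue
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 0:
            fitted[gi] = ym
            continue
        beta = (w * (x - xm) * (y - ym)).sum() / sxx
        fitted[gi] = ym + beta * (x0 - xm)
    return grid, fitted


# ---------------------------------------------------------------------------
# capture-model recovery


@dataclass
class CaptureModelFit:
    """Logistic retention fit to per-window capture/shotgun depth ratios."""

    id_50: float
    slope: float
    amplitude: float
    ci_id_50: tuple[float, float]
    ci_slope: tuple[float, float]
    n_windows: int
    n_boot: int


def _logistic(x, amplitude, id_50, slope):
    return amplitude / (1.0 + np.exp(-slope * (x - id_50)))


def fit_capture_model(
    wins: Sequence[WindowStat],
    n_boot: int = 200,
    seed: int = 0,
    block: int = 5,
) -> CaptureModelFit:
    """Recover the logistic retention curve from windowed depth ratios.

    Least-squares fit of ``ratio = A / (1 + exp(-slope*(identity - id_50)))``
    to per-window capture/shotgun depth ratios (gap-flagged windows and
    windows with zero shotgun depth excluded); the amplitude A absorbs the
    capture/shotgun library-size ratio, so ``id_50`` and ``slope`` are the
    interpretable parameters.  Percentile bootstrap intervals come from a
    moving-block bootstrap (blocks of ``block`` consecutive windows), which
    respects the correlation between overlapping windows; an ordinary
    i.i.d. window bootstrap would understate the interval.  Degenerate
    input — all windows at one divergence, or a flat ratio profile — is
    rejected.
    """
    clean = [w for w in wins if not w.has_gap and w.depth_shotgun > 0 and np.isfinite(w.identity)]
    ident = np.array([w.identity for w in clean])
    ratio = np.array([w.depth_capture / w.depth_shotgun for w in clean])
    if len(clean) < 5:
        raise ValueError("too few usable windows for a fit")
    n_bins = len(set(np.floor((1 - ident) / 0.02).astype(int)))
    if n_bins < 3 or np.ptp(ident) < 1e-9:
        raise ValueError("degenerate spread: windows span too few divergence levels")
    if np.ptp(ratio) < 1e-9 * max(1.0, np.abs(ratio).max()):
        raise ValueError("degenerate spread: flat capture/shotgun ratio profile")

    def fit_once(xi, ri):
        amp0 = max(ri.max(), 1e-6)
        # initial midpoint: identity where the ratio first falls below amp0/2
        order = np.argsort(xi)[::-1]
        below = ri[order] < amp0 / 2
        id0 = xi[order][below][0] if below.any() else float(np.median(xi))
        p0 = [amp0, float(np.clip(id0, 0.05, 0.95)), 20.0]
        popt, _ = curve_fit(
            _logistic, xi, ri, p0=p0,
            bounds=([1e-9, 0.0, 0.1], [np.inf, 1.0, 1000.0]),
            maxfev=20000,
        )
        return popt

    amp, id_50, slope = fit_once(ident, ratio)
    rng = np.random.default_rng(seed)
    n = len(clean)
    block = max(1, min(block, n))
    n_blocks = int(np.ceil(n / block))
    boot_id, boot_slope = [], []
    for _ in range(n_boot):
        starts = rng.integers(0, n - block + 1, size=n_blocks)
        idx = (starts[:, None] + np.arange(block)).ravel()[:n]
        try:
            _, bi, bs = fit_once(ident[idx], ratio[idx])
        except RuntimeError:
            continue
        boot_id.append(bi)
        boot_slope.append(bs)
    if boot_id:
        ci_id = (float(np.percentile(boot_id, 2.5)), float(np.percentile(boot_id, 97.5)))
        ci_slope = (float(np.percentile(boot_slope, 2.5)), float(np.percentile(boot_slope, 97.5)))
    else:
        ci_id = (float("nan"), float("nan"))
        ci_slope = (float("nan"), float("nan"))
    return CaptureModelFit(
        id_50=float(id_50), slope=float(slope), amplitude=float(amp),
        ci_id_50=ci_id, ci_slope=ci_slope, n_windows=len(clean), n_boot=len(boot_id),
    )


# ---------------------------------------------------------------------------
# output


def write_window_bed(wins: Sequence[WindowStat], ref_id: str, path: str | Path) -> None:
    """Windows as BED: chrom, start, end, divergence, depth_capture, depth_shotgun."""
    with open(path, "w") as fh:
        for w in wins:
            fh.write(
                f"{ref_id}\t{w.start}\t{w.end}\t{w.divergence:.6f}\t"
                f"{w.depth_capture:.4f}\t{w.depth_shotgun:.4f}\n"
            )


def plot_response(table: pd.DataFrame, path: str | Path, span: float = 0.5) -> None:
    """Bar-and-trendline figure: window share per divergence bin (bars) and
    capture/shotgun depth shares (points with tricube trendlines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mid = (table["bin_low"] + table["bin_high"]) / 2
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.bar(mid, table["prop_windows"], width=0.8 * (table["bin_high"] - table["bin_low"]),
           color="0.8", edgecolor="0.5", label="windows")
    for col, color in (("prop_capture", "tab:orange"), ("prop_shotgun", "black")):
        ax.plot(mid, table[col], "o", color=color, ms=4, label=col.replace("prop_", ""))
        ok = table[col].notna()
        if ok.sum() >= 5:
            g, f = loess_trend(mid[ok].to_numpy(), table.loc[ok, col].to_numpy(), span=span)
            ax.plot(g, f, "-", color=color, lw=1.5)
    ax.set_xlabel("bait-to-target divergence")
    ax.set_ylabel("proportion")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
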
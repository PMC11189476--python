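"""Single-channel amplitude analysis.

Workflow for cell-attached / inside-out patch recordings: Gaussian
low-pass filtering (-3 dB at the requested cutoff), amplitude
histograms, a sum-of-Gaussians fit of the histogram

    f(x) = sum_i alpha_i * exp(-((x - beta_i) * gamma_i)^2)

whose components map algebraically onto scaled normal densities with
mu_i = beta_i, sigma_i = (2 gamma_i^2)^(-1/2) and area
rho_i = sqrt(pi) * alpha_i / gamma_i, state event fractions from the
component areas, unitary conductance from the open-closed level
separation, and an NPo time course from half-amplitude idealisation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, signal

from .core import AmplitudeHistogram, ChannelTrace, GaussianSumModel, StateFractions

__all__ = [
    "gaussian_lowpass",
    "amplitude_histogram",
    "fit_gaussian_sum",
    "derive_params",
    "state_fractions",
    "unitary_conductance",
    "npo_timecourse",
    "idealise_half_amplitude",
    "NPoResult",
]

# sigma_t = sqrt(ln 2) / (2 pi f_c): Gaussian FIR whose -3 dB point is f_c
_SIGMA_T_COEFF = math.sqrt(math.log(2.0)) / (2.0 * math.pi)  # = 0.13249...


def gaussian_lowpass(trace: ChannelTrace, cutoff: float) -> ChannelTrace:
    """Low-pass Gaussian FIR filter with -3 dB attenuation at ``cutoff`` Hz.

    The kernel standard deviation in time is sigma_t = 0.1325 / f_c (so
    the transfer function drops to 1/sqrt(2) at f_c); the filter is
    zero-phase and edges are handled by reflection.
    """
    if cutoff >= trace.sample_rate / 2:
        raise ValueError("filter cutoff must be below the Nyquist frequency")
    if cutoff <= 0:
        raise ValueError("filter cutoff must be positive")
    sigma_samples = _SIGMA_T_COEFF / cutoff * trace.sample_rate
    filtered = ndimage.gaussian_filter1d(trace.current, sigma_samples, mode="reflect")
    info = dict(trace.filter_info)
    info.update(
        {"type": "gaussian", "cutoff_hz": float(cutoff), "sigma_samples": float(sigma_samples)}
    )
    return ChannelTrace(
        current=filtered,
        sample_rate=trace.sample_rate,
        holding_potential=trace.holding_potential,
        filter_info=info,
        state_path=trace.state_path,
        state_levels=trace.state_levels,
    )


def amplitude_histogram(trace: ChannelTrace, bin_width: float = 0.05) -> AmplitudeHistogram:
    """All-points amplitude histogram with uniform bins of ``bin_width`` pA.

    Counts are kept linear; logarithmic display of the counts axis is a
    presentation choice and does not change the fit input.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    lo = float(trace.current.min())
    hi = float(trace.current.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(trace.current, bins=edges)
    return AmplitudeHistogram(edges=edges, counts=counts)


def _sum_of_gaussians(x: np.ndarray, *params: float) -> np.ndarray:
    p = np.asarray(params).reshape(3, -1)
    alpha, beta, gamma = p
    arg = (x[:, None] - beta) * gamma
    return np.sum(alpha * np.exp(-(arg**2)), axis=1)


def _initial_guess(hist: AmplitudeHistogram, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Peak-picking initialisation: the n tallest well-separated peaks."""
    centres = hist.centres
    counts = hist.counts.astype(float)
    smoothed = ndimage.gaussian_filter1d(counts, 1.0)
    # rough scale of a component from the overall spread
    weights = counts / counts.sum() if counts.sum() > 0 else None
    spread = np.sqrt(np.average((centres - np.average(centres, weights=weights)) ** 2,
                                weights=weights)) if weights is not None else np.ptp(centres)
    sigma0 = max(spread / max(n, 1), (centres[1] - centres[0]) if centres.size > 1 else 1.0)
    min_sep = max(1, int(round(2.0 * sigma0 / (centres[1] - centres[0])))) if centres.size > 1 else 1
    peaks, props = signal.find_peaks(smoothed, distance=min_sep)
    if peaks.size:
        order = np.argsort(smoothed[peaks])[::-1]
        peaks = peaks[order[:n]]
        # ties and ordering resolved toward lower amplitude
        peaks = np.sort(peaks)
    if peaks.size < n:
        qs = np.linspace(0.1, 0.9, n)
        extra = np.quantile(centres, qs)
        beta0 = np.sort(np.concatenate([centres[peaks], extra]))[:n]
        alpha0 = np.interp(beta0, centres, np.maximum(smoothed, 1.0))
    else:
        beta0 = centres[peaks]
        alpha0 = np.maximum(smoothed[peaks], 1.0)
    gamma0 = np.full(n, 1.0 / (math.sqrt(2.0) * sigma0))
    return alpha0, beta0, gamma0


def fit_gaussian_sum(
    hist: AmplitudeHistogram,
    n: int,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> GaussianSumModel:
    """Non-linear least-squares fit of a sum of n Gaussians to a histogram.

    The fit minimises the residual between the model and the (bin
    centre, count) pairs, with bounds alpha >= 0 and gamma > 0.
    Components are returned sorted by increasing |beta|. A fit that does
    not converge is flagged but its parameters are still returned.
    """
    if n < 1:
        raise ValueError("need at least one component")
    occupied = int(np.count_nonzero(hist.counts))
    if occupied < 3 * n:
        warnings.warn(
            f"{n} components may exceed what {occupied} occupied bins can resolve",
            stacklevel=2,
        )
    alpha0, beta0, gamma0 = init if init is not None else _initial_guess(hist, n)
    p0 = np.concatenate([alpha0, beta0, gamma0]).astype(float)
    span = hist.edges[-1] - hist.edges[0]
    lower = np.concatenate([np.zeros(n), np.full(n, hist.edges[0] - span),
                            np.full(n, 1e-9)])
    upper = np.concatenate([np.full(n, np.inf), np.full(n, hist.edges[-1] + span),
                            np.full(n, np.inf)])
    p0 = np.clip(p0, lower + 1e-12, np.where(np.isinf(upper), p0, upper))
    x = hist.centres
    y = hist.counts.astype(float)

    converged = True
    try:
        popt, _ = optimize.curve_fit(
            _sum_of_gaussians, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError:
        converged = False
        res = optimize.least_squares(
            lambda p: _sum_of_gaussians(x, *p) - y, p0, bounds=(lower, upper)
        )
        popt = res.x
    alpha, beta, gamma = np.asarray(popt).reshape(3, n)
    order = np.argsort(np.abs(beta))
    alpha, beta, gamma = alpha[order], beta[order], gamma[order]
    residual = float(np.sqrt(np.mean((_sum_of_gaussians(x, *np.concatenate([alpha, beta, gamma])) - y) ** 2)))
    model = GaussianSumModel(
        alpha=alpha, beta=beta, gamma=gamma, residual=residual, converged=converged
    )
    return derive_params(model)


def derive_params(model: GaussianSumModel) -> GaussianSumModel:
    """Populate mu, sigma, rho from alpha, beta, gamma.

    mu = beta, sigma = (2 gamma^2)^(-1/2), rho = sqrt(pi) * alpha / gamma
    (rho is the area of the component, in count * pA). The two model
    forms agree pointwise after this mapping.
    """
    model.mu = model.beta.copy()
    model.sigma = (2.0 * model.gamma**2) ** (-0.5)
    model.rho = math.sqrt(math.pi) * model.alpha / model.gamma
    return model


def _label_components(model: GaussianSumModel, baseline: float) -> list[str]:
    mu = model.mu
    closed = int(np.argmin(np.abs(mu - baseline)))
    open_ = int(np.argmax(np.abs(mu - baseline)))
    labels = []
    s = 1
    for i in range(model.n):
        if i == closed:
            labels.append("c")
        elif i == open_:
            labels.append("o")
        else:
            labels.append(f"s{s}")
            s += 1
    return labels


def state_fractions(model: GaussianSumModel, baseline: float = 0.0) -> StateFractions:
    """Event fractions per state class from the component areas.

    fraction_i = rho_i / sum(rho). The component with mu nearest the
    baseline is the closed state, the one farthest from it the fully
    open state, anything between a sublevel. Components whose means are
    within one sigma of each other make the labelling ambiguous, which
    is flagged rather than hidden.
    """
    if model.rho is None:
        model = derive_params(model)
    labels = _label_components(model, baseline)
    model.labels = labels
    total = model.rho.sum()
    if total <= 0:
        raise ValueError("model has zero total area")
    fr = model.rho / total
    fractions = {lab: float(f) for lab, f in zip(labels, fr)}
    by_class = {
        "closed": float(sum(f for lab, f in zip(labels, fr) if lab == "c")),
        "sub": float(sum(f for lab, f in zip(labels, fr) if lab.startswith("s"))),
        "open": float(sum(f for lab, f in zip(labels, fr) if lab == "o")),
    }
    ambiguous = False
    order = np.argsort(model.mu)
    mus, sigmas = model.mu[order], model.sigma[order]
    for i in range(model.n - 1):
        if mus[i + 1] - mus[i] < max(sigmas[i], sigmas[i + 1]):
            ambiguous = True
    return StateFractions(fractions=fractions, by_class=by_class, ambiguous=ambiguous)


def unitary_conductance(model: GaussianSumModel, potential: float) -> float:
    """Unitary conductance in pS from the open-closed separation.

    gamma_unitary = (mu_open - mu_closed) / V, with pA/mV converted to pS
    (x 1000). Requires the components to be labelled (run
    :func:`state_fractions` first or label manually). Insensitive to a DC
    offset on the trace since only the mu difference enters.
    """
    if potential == 0:
        raise ValueError("potential must be non-zero")
    if model.labels is None or model.mu is None:
        raise ValueError("model must be labelled; call state_fractions first")
    mu_c = model.mu[model.labels.index("c")]
    # a one-component model has no separate open level: zero separation
    mu_o = model.mu[model.labels.index("o")] if "o" in model.labels else mu_c
    return float((mu_o - mu_c) / potential * 1000.0)


def idealise_half_amplitude(trace: ChannelTrace, model: GaussianSumModel) -> np.ndarray:
    """Assign each sample to a fitted level by half-amplitude thresholds.

    Levels are the fitted component means sorted along the conduction
    direction from closed; thresholds sit midway between adjacent means.
    Returns the per-sample index into the sorted level array (0 = closed).
    """
    if model.mu is None or model.labels is None:
        raise ValueError("model must be labelled; call state_fractions first")
    mu_c = model.mu[model.labels.index("c")]
    mu_o = model.mu[model.labels.index("o")]
    direction = 1.0 if mu_o >= mu_c else -1.0
    rel_levels = np.sort((model.mu - mu_c) * direction)
    thresholds = 0.5 * (rel_levels[:-1] + rel_levels[1:])
    rel = (trace.current - mu_c) * direction
    return np.digitize(rel, thresholds)


@dataclass
class NPoResult:
    """Windowed NPo estimates."""

    window_starts: np.ndarray  # s
    npo: np.ndarray
    window: float  # s


def npo_timecourse(
    trace: ChannelTrace, model: GaussianSumModel, window: float = 1.0
) -> NPoResult:
    """NPo per consecutive time window from half-amplitude idealisation.

    Each sample contributes a weight equal to its level's fractional
    conductance (mu_level - mu_closed)/(mu_open - mu_closed); sublevels
    therefore count in proportion to their amplitude, closed counts 0
    and fully open counts 1. NPo over a window is the mean weight.
    """
    n_win_samples = int(round(window * trace.sample_rate))
    if n_win_samples < 100:
        raise ValueError("window must contain at least 100 samples")
    if model.mu is None or model.labels is None:
        raise ValueError("model must be labelled; call state_fractions first")
    mu_c = model.mu[model.labels.index("c")]
    mu_o = model.mu[model.labels.index("o")]
    direction = 1.0 if mu_o >= mu_c else -1.0
    rel_levels = np.sort((model.mu - mu_c) * direction)
    rel_open = (mu_o - mu_c) * direction
    if rel_open <= 0:
        raise ValueError("open and closed levels coincide")
    weights = np.clip(rel_levels / rel_open, 0.0, None)
    level_idx = idealise_half_amplitude(trace, model)
    w = weights[level_idx]
    n_windows = trace.n_samples // n_win_samples
    if n_windows == 0:
        raise ValueError("trace shorter than one window")
    w = w[: n_windows * n_win_samples].reshape(n_windows, n_win_samples)
    return NPoResult(
        window_starts=np.arange(n_windows) * window,
        npo=w.mean(axis=1),
        window=window,
    )
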
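"""Canonical hemodynamic response function and design-regressor construction.

The double-gamma HRF (response peak 6 s, undershoot peak 16 s, undershoot
ratio 1/6) is the field-standard impulse response for modelling the BOLD
signal evoked by a task boxcar.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .timeline import DesignTimeline


def double_gamma_hrf(
    dt: float,
    duration_s: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Sampled double-gamma HRF, unit-sum normalized.

    With dispersions of 1 the response and undershoot gamma densities have
    shapes ``peak_delay`` and ``undershoot_delay``, placing their modes at
    ~(delay - 1) s; this matches the canonical SPM/Glover parameterization.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration_s, dt)

    def gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
        with np.errstate(divide="ignore"):
            logpdf = (
                (shape - 1.0) * np.log(np.maximum(t, 1e-300))
                - t / scale
                - shape * np.log(scale)
                - gammaln(shape)
            )
        out = np.exp(logpdf)
        out[t <= 0] = 0.0
        return out

    h = gamma_pdf(t, peak_delay / peak_disp, peak_disp) - undershoot_ratio * gamma_pdf(
        t, undershoot_delay / undershoot_disp, undershoot_disp
    )
    s = h.sum()
    if s != 0:
        h = h / s
    return h


def build_design_regressor(
    timeline: DesignTimeline,
    tr: float,
    n_drop: int = 0,
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved block regressor sampled at volume midpoints.

    The fixation/movement boxcar is built on a fine grid (``dt``), convolved
    with the canonical HRF, sampled at volume midpoints, and the first
    ``n_drop`` volumes are removed to align with the trimmed data.
    """
    n_volumes = timeline.n_volumes(tr)
    if n_drop >= n_volumes:
        raise ValueError("n_drop must be smaller than the number of volumes")
    t_fine = np.arange(0.0, timeline.total_duration_s, dt)
    box = np.array([1.0 if timeline.label_at(t) == timeline.phases[0].label else 0.0
                    for t in t_fine])
    # phases[0] is fixation; invert so movement == 1
    box = 1.0 - box
    h = double_gamma_hrf(dt)
    conv = np.convolve(box, h)[: t_fine.size]
    mids = (np.arange(n_volumes) + 0.5) * tr
    idx = np.clip(np.round(mids / dt).astype(int), 0, t_fine.size - 1)
    reg = conv[idx]
    return reg[n_drop:]
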
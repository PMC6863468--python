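"""Shared test utilities: degenerate truths and an independent brute-force
oracle for the curve fit."""

import numpy as np

from rdacclim.synthetic import TrueParameters


def zero_variance_truth(**overrides) -> TrueParameters:
    """Deterministic truth: no noise, no offsets, no temperature jitter."""
    kw = dict(species_offset_sd=0.0, individual_offset_sd=0.0,
              noise_sd_log=0.0, top_temp_jitter_sd=0.0)
    kw.update(overrides)
    return TrueParameters(**kw)


def strong_acclimation_trends():
    """Truth with strong non-photosynthetic acclimation and none in
    photosynthetic tissues: the root basal parameter drifts at exactly the
    rate that keeps R_d(T_a; T_a) constant (perfect homeostasis), the
    non-photosynthetic stem at 80% of that rate, while leaf and
    photosynthetic stem parameters ignore T_a entirely."""
    flat = {"b": (0.1, 0.0), "c": (0.0, 0.0)}
    return {
        "leaf": {"a": (-6.5, 0.0), **flat},
        "ps_stem": {"a": (-6.5, 0.0), **flat},
        "nonps_stem": {"a": (-6.5 + 0.08 * 25.0, -0.08), **flat},
        "root": {"a": (-6.5 + 0.1 * 25.0, -0.1), **flat},
    }


def grid_search_log_sse(T, rate, spacing=1e-4):
    """Brute-force oracle: minimise the log-scale SSE of the
    exponential-quadratic model over an (a, b, c) lattice, iteratively
    refined to the requested spacing.  Independent of the closed-form fit.
    """
    T = np.asarray(T, float)
    logy = np.log(np.asarray(rate, float))

    centre = np.array([-6.0, 0.1, -0.001])
    width = np.array([8.0, 0.4, 0.02])
    npts = 9
    while True:
        axes = [np.linspace(c - w, c + w, npts) for c, w in zip(centre, width)]
        A, B, C = np.meshgrid(*axes, indexing="ij")
        pred = (A[..., None] + B[..., None] * T + C[..., None] * T * T)
        sse = np.sum((pred - logy) ** 2, axis=-1)
        idx = np.unravel_index(np.argmin(sse), sse.shape)
        best = np.array([axes[k][idx[k]] for k in range(3)])
        centre = best
        if any(i in (0, npts - 1) for i in idx):
            width = width * 2.0  # optimum on the box edge: expand
        else:
            if np.all(2 * width / (npts - 1) < spacing):
                return best, float(np.min(sse))
            width = width / 3.0
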
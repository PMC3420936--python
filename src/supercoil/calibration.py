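"""Calibration of the in vivo supercoil sensor response curve.

The gamma-delta resolution assay reads out diffusible negative supercoil
density sigma_D through the fraction of cells that delete a chromosomal
sensor: synapsis of the two Res sites needs supercoil-driven slithering and
branching, so resolution efficiency R rises monotonically with |sigma_D|.
Three response anchors are fixed by the assay itself: R falls to zero on
relaxed DNA (sigma_D >= -0.004), R = 50% at sigma_D = -0.030, and R
saturates near 100% by sigma_D <= -0.040.

The default fitted form is an asymmetric generalized logistic (Richards)

    R(sigma) = (1 + exp((sigma - sigma0) / w)) ** (-nu),    nu = 0.5,

hard-clamped to 0 for sigma >= sigma_relaxed.  The asymmetry is required:
the printed efficiency -> sigma_D mappings approach saturation much more
steeply than they leave the detection limit, and a symmetric logistic cannot
reproduce both ends within the +-0.003 supercoil-density tolerance that the
rounded tables support.  The form has an analytic inverse, so inversion of
measured efficiencies into apparent sigma_D is exact.  A shape-preserving
monotone cubic (PCHIP) through the same points is available with
``method="pchip"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

__all__ = [
    "CalibrationCurve", "SigmaEstimate", "DEFAULT_ANCHORS",
    "fit_calibration", "efficiency_at", "sigma_from_efficiency",
    "total_sigma", "delta_sigma", "curve_to_json", "curve_from_json",
    "read_pairs_tsv", "write_pairs_tsv",
]

#: (efficiency fraction, sigma_D) anchors stated for the assay response.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (0.0, -0.004),   # relaxed DNA cannot drive synapsis
    (0.5, -0.030),   # half-maximal resolution
    (0.95, -0.040),  # saturation
)

SIGMA_MIN = -0.06            # most negative sigma_D the assay resolves
DETECTION_LIMIT = 0.01       # efficiency below which only a bound is known
DETECTION_SIGMA_BOUND = -0.003   # |sigma_D| bound reported for censored rows
SATURATION_EFF = 0.95        # efficiency above which inversion saturates
SATURATION_SIGMA_CAP = -0.045   # extrapolation cap on saturated inversions
_RICHARDS_SHAPE = 0.5


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted monotone map between sigma_D and resolution efficiency."""

    method: str                      # "richards" | "pchip"
    sigma0: float                    # Richards location parameter
    width: float                     # Richards width (supercoil-density units)
    shape: float                     # Richards asymmetry exponent nu
    sigma_relaxed: float             # efficiency clamped to 0 at/above this
    sigma_half: float                # sigma_D at 50% efficiency (fitted)
    sigma_saturation: float          # sigma_D at/below which efficiency >= 0.90
    fitted_pairs: tuple[tuple[float, float], ...]
    fit_residual: float              # RMS residual, efficiency units
    _nodes_sigma: tuple[float, ...] = field(default=(), repr=False)
    _nodes_eff: tuple[float, ...] = field(default=(), repr=False)

    def efficiency(self, sigma):
        return efficiency_at(self, sigma)

    def _pchip_forward(self) -> PchipInterpolator:
        return PchipInterpolator(np.array(self._nodes_sigma),
                                 np.array(self._nodes_eff))

    def _pchip_inverse(self) -> PchipInterpolator:
        # nodes are strictly monotone: eff decreasing in sigma
        e = np.array(self._nodes_eff)[::-1]
        s = np.array(self._nodes_sigma)[::-1]
        return PchipInterpolator(e, s)


@dataclass(frozen=True)
class SigmaEstimate:
    """Apparent sigma_D inferred from one resolution efficiency.

    ``kind`` is "point" for an interior inversion, "magnitude_upper_bound"
    when efficiency is below the detection limit (the DNA is at most weakly
    supercoiled), and "magnitude_lower_bound" when efficiency is saturated
    and only a floor on |sigma_D| is supported.
    """

    value: float
    kind: str
    source_efficiency: float
    saturated: bool = False

    def __post_init__(self):
        if not (SIGMA_MIN - 1e-12 <= self.value <= 0.0):
            raise ValueError(f"sigma_D estimate {self.value} outside "
                             f"[{SIGMA_MIN}, 0]")


def _richards(sigma, sigma0, width, shape):
    z = np.clip((np.asarray(sigma, float) - sigma0) / width, -500, 500)
    return (1.0 + np.exp(z)) ** (-shape)


def _richards_inverse(eff, sigma0, width, shape):
    return sigma0 + width * np.log(np.asarray(eff, float) ** (-1.0 / shape) - 1.0)


def _check_pairs(pairs):
    for eff, sig in pairs:
        if not 0.0 <= eff <= 1.0:
            raise ValueError(f"efficiency {eff} outside [0, 1]")
        if sig > 0.0:
            raise ValueError(f"sigma_D {sig} is positive; supercoil density "
                             "must be <= 0")
        if sig < SIGMA_MIN:
            raise ValueError(f"sigma_D {sig} below assay range {SIGMA_MIN}")


def _monotone_warning(pairs, tol=0.08):
    srt = sorted(pairs, key=lambda p: p[1])   # ascending sigma (toward 0)
    for (e0, s0), (e1, s1) in zip(srt, srt[1:]):
        if e1 - e0 > tol and s1 > s0:
            warnings.warn(
                f"pairs ({e0}, {s0}) and ({e1}, {s1}) demand efficiency to "
                "rise toward relaxed DNA; fit proceeds but residual will "
                "reflect the conflict", stacklevel=3)
            return


def fit_calibration(pairs, anchors=DEFAULT_ANCHORS, *, method="richards",
                    anchor_weight=5.0) -> CalibrationCurve:
    """Fit the monotone response curve to observed (efficiency, sigma_D) pairs.

    Anchors are included in the least-squares target at ``anchor_weight``
    times the weight of the observations, since they are stated exactly while
    table pairs are rounded.  Requires at least 3 points overall.
    """
    pairs = [tuple(map(float, p)) for p in pairs]
    anchors = [tuple(map(float, a)) for a in anchors]
    _check_pairs(pairs)
    _check_pairs(anchors)
    if len(pairs) + len(anchors) < 3:
        raise ValueError("need at least 3 (efficiency, sigma_D) points")
    _monotone_warning(pairs + anchors)

    effs = np.array([p[0] for p in pairs] + [a[0] for a in anchors])
    sigs = np.array([p[1] for p in pairs] + [a[1] for a in anchors])
    wts = np.array([1.0] * len(pairs) + [anchor_weight] * len(anchors))
    sigma_relaxed = -0.004

    if method == "richards":
        def model(sig, s0, w):
            r = _richards(sig, s0, w, _RICHARDS_SHAPE)
            return np.where(sig >= sigma_relaxed, 0.0, r)

        def resid(theta):
            return np.sqrt(wts) * (model(sigs, theta[0], np.exp(theta[1])) - effs)

        sol = least_squares(resid, x0=[-0.033, np.log(0.004)])
        sigma0, width = sol.x[0], float(np.exp(sol.x[1]))
        shape = _RICHARDS_SHAPE
        fitted = model(sigs, sigma0, width)
        sigma_half = float(_richards_inverse(0.5, sigma0, width, shape))
        sigma_sat = float(_richards_inverse(0.90, sigma0, width, shape))
        nodes_s, nodes_e = (), ()
    elif method == "pchip":
        nodes_s, nodes_e = _monotone_nodes(effs, sigs)
        interp = PchipInterpolator(np.array(nodes_s), np.array(nodes_e))
        fitted = np.where(sigs >= sigma_relaxed, 0.0, interp(sigs))
        inv = PchipInterpolator(np.array(nodes_e)[::-1], np.array(nodes_s)[::-1])
        sigma0, width, shape = float("nan"), float("nan"), float("nan")
        sigma_half = float(inv(0.5))
        sigma_sat = float(inv(0.90))
    else:
        raise ValueError(f"unknown method {method!r}; use 'richards' or 'pchip'")

    residual = float(np.sqrt(np.average((fitted - effs) ** 2, weights=wts)))
    return CalibrationCurve(
        method=method, sigma0=float(sigma0), width=width, shape=shape,
        sigma_relaxed=sigma_relaxed, sigma_half=sigma_half,
        sigma_saturation=float(sigma_sat),
        fitted_pairs=tuple(pairs), fit_residual=residual,
        _nodes_sigma=tuple(nodes_s), _nodes_eff=tuple(nodes_e),
    )


def _monotone_nodes(effs, sigs):
    """Pool observations into a strictly monotone node set for PCHIP."""
    order = np.argsort(sigs)
    s, e = np.asarray(sigs)[order], np.asarray(effs)[order]
    # average duplicates in sigma
    us, inv = np.unique(np.round(s, 10), return_inverse=True)
    ue = np.array([e[inv == i].mean() for i in range(len(us))])
    # pool-adjacent-violators so efficiency is non-increasing in sigma
    blocks = [[ue[i], 1.0, us[i]] for i in range(len(us))]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i + 1][0] > blocks[i][0]:
            v0, w0, _ = blocks[i]
            v1, w1, _ = blocks[i + 1]
            blocks[i][0] = (v0 * w0 + v1 * w1) / (w0 + w1)
            blocks[i][1] = w0 + w1
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    nodes_s, nodes_e, last = [], [], None
    for v, _, s_rep in blocks:
        if last is not None and v >= last:
            v = last - 1e-9
        nodes_s.append(float(s_rep))
        nodes_e.append(float(min(max(v, 0.0), 1.0)))
        last = v
    return tuple(nodes_s), tuple(nodes_e)


def efficiency_at(curve: CalibrationCurve, sigma):
    """Resolution efficiency predicted at supercoil density ``sigma``.

    Clamped to 0 for sigma at or above ``curve.sigma_relaxed`` (relaxed DNA);
    saturates toward 1 below ``curve.sigma_saturation``.
    """
    arr = np.asarray(sigma, float)
    if np.any(arr > 0):
        raise ValueError("sigma_D must be <= 0 (negative supercoiling)")
    if curve.method == "richards":
        eff = _richards(arr, curve.sigma0, curve.width, curve.shape)
    else:
        eff = np.clip(curve._pchip_forward()(arr), 0.0, 1.0)
    out = np.where(arr >= curve.sigma_relaxed, 0.0, eff)
    return float(out) if np.isscalar(sigma) or arr.ndim == 0 else out


def sigma_from_efficiency(curve: CalibrationCurve, eff: float) -> SigmaEstimate:
    """Invert a measured resolution efficiency into an apparent sigma_D.

    Efficiencies below the detection limit yield a magnitude upper bound
    (|sigma_D| <= 0.003); saturated efficiencies (>= 0.95) are inverted but
    the extrapolation is capped at -0.045 and flagged.
    """
    eff = float(eff)
    if not 0.0 <= eff <= 1.0:
        raise ValueError(f"efficiency {eff} outside [0, 1]")
    if eff < DETECTION_LIMIT:
        return SigmaEstimate(value=DETECTION_SIGMA_BOUND,
                             kind="magnitude_upper_bound",
                             source_efficiency=eff)
    if curve.method == "richards":
        raw = float(_richards_inverse(min(eff, 1.0 - 1e-12),
                                      curve.sigma0, curve.width, curve.shape))
    else:
        raw = float(curve._pchip_inverse()(eff))
    if eff >= SATURATION_EFF:
        if raw < SATURATION_SIGMA_CAP:
            return SigmaEstimate(value=SATURATION_SIGMA_CAP,
                                 kind="magnitude_lower_bound",
                                 source_efficiency=eff, saturated=True)
        return SigmaEstimate(value=max(raw, SIGMA_MIN), kind="point",
                             source_efficiency=eff, saturated=True)
    value = float(np.clip(raw, SIGMA_MIN, curve.sigma_relaxed))
    return SigmaEstimate(value=value, kind="point", source_efficiency=eff)


def total_sigma(sigma_constrained: float, sigma_diffusible: float) -> float:
    """Total supercoil density sigma = sigma_C + sigma_D."""
    if sigma_constrained > 0 or sigma_diffusible > 0:
        raise ValueError("supercoil densities must be <= 0")
    return sigma_constrained + sigma_diffusible


def delta_sigma(curve: CalibrationCurve, eff_before: float,
                eff_after: float) -> float:
    """Change in apparent sigma_D between two conditions of one sensor.

    Censored inputs (below the detection limit) enter through their bound
    magnitude, so a "<1% -> 57%" rebound is measured from sigma_D = -0.003.
    """
    before = sigma_from_efficiency(curve, eff_before)
    after = sigma_from_efficiency(curve, eff_after)
    return after.value - before.value


# -- serialization ----------------------------------------------------------

def curve_to_json(curve: CalibrationCurve) -> str:
    """Serialize a fitted curve to JSON text (exact float round-trip)."""
    d = {
        "form": curve.method,
        "sigma0": curve.sigma0, "width": curve.width, "shape": curve.shape,
        "sigma_relaxed": curve.sigma_relaxed, "sigma_half": curve.sigma_half,
        "sigma_saturation": curve.sigma_saturation,
        "fitted_pairs": [list(p) for p in curve.fitted_pairs],
        "fit_residual": curve.fit_residual,
        "nodes_sigma": list(curve._nodes_sigma),
        "nodes_eff": list(curve._nodes_eff),
    }
    return json.dumps(d, indent=2, sort_keys=True)


def curve_from_json(text: str) -> CalibrationCurve:
    d = json.loads(text)
    return CalibrationCurve(
        method=d["form"], sigma0=d["sigma0"], width=d["width"],
        shape=d["shape"], sigma_relaxed=d["sigma_relaxed"],
        sigma_half=d["sigma_half"], sigma_saturation=d["sigma_saturation"],
        fitted_pairs=tuple(tuple(p) for p in d["fitted_pairs"]),
        fit_residual=d["fit_residual"],
        _nodes_sigma=tuple(d["nodes_sigma"]),
        _nodes_eff=tuple(d["nodes_eff"]),
    )


def read_pairs_tsv(path) -> list[tuple[float, float]]:
    """Read (efficiency_fraction, sigma_d) pairs from 2-column TSV."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["efficiency_fraction"].astype(float),
                    df["sigma_d"].astype(float)))


def write_pairs_tsv(pairs, path) -> None:
    import pandas as pd
    pd.DataFrame(pairs, columns=["efficiency_fraction", "sigma_d"]).to_csv(
        path, sep="\t", index=False)
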
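"""Orthogonal wavelet machinery: sym8/Haar filter banks, decimated multilevel
DWT, MODWT, multiresolution reconstruction, and universal-threshold denoising.

The decimated transform delegates to PyWavelets using the filter banks
embedded below; the maximal overlap discrete wavelet transform (MODWT) and
its inverse are implemented here directly with the circular pyramid
algorithm, since the undecimated transform PyWavelets ships (``swt``) uses a
different normalization. MODWT coefficient sequences all keep the input
length and the transform is exactly shift-equivariant, which is what makes
it the right front end for R-peak localisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

# ---------------------------------------------------------------------------
# Filter banks

#: Symlet-8 scaling (low-pass) coefficients, 16 taps, 8 vanishing moments.
#: Embedded as constants and validated at import time by the quadrature
#: identities below, so the bank has no external coefficient source.
SYM8_H = (
    -0.0033824159510061256,
    -0.0005421323317911481,
    0.03169508781149298,
    0.007607487324917605,
    -0.1432942383508097,
    -0.061273359067658524,
    0.4813596512583722,
    0.7771857517005235,
    0.3644418948353314,
    -0.05194583810770904,
    -0.027219029917056003,
    0.049137179673607506,
    0.003808752013890615,
    -0.01495225833704823,
    -0.0003029205147213668,
    0.0018899503327594609,
)

HAAR_H = (0.7071067811865476, 0.7071067811865476)


@dataclass(frozen=True)
class WaveletFilterBank:
    """An orthogonal two-channel filter bank.

    ``h`` is the scaling (low-pass) filter; the wavelet (high-pass) filter is
    derived by the quadrature-mirror relation g[k] = (-1)^k h[L-1-k].
    """

    name: str
    h: np.ndarray
    n_vanishing_moments: int

    def __post_init__(self):
        object.__setattr__(self, "h", np.asarray(self.h, dtype=float))
        self.validate()

    @property
    def g(self) -> np.ndarray:
        L = len(self.h)
        signs = (-1.0) ** np.arange(L)
        return signs * self.h[::-1]

    def validate(self, tol: float = 1e-12) -> None:
        h = np.asarray(self.h, dtype=float)
        if abs(h.sum() - np.sqrt(2.0)) > tol:
            raise ValueError(f"{self.name}: sum(h) != sqrt(2)")
        if abs((h ** 2).sum() - 1.0) > tol:
            raise ValueError(f"{self.name}: sum(h^2) != 1")
        if len(h) % 2 != 0:
            raise ValueError(f"{self.name}: filter length must be even")

    def to_pywt(self) -> pywt.Wavelet:
        dec_lo = list(self.h)
        dec_hi = list(self.g)
        return pywt.Wavelet(
            self.name,
            filter_bank=[dec_lo, dec_hi, dec_lo[::-1], dec_hi[::-1]],
        )


SYM8 = WaveletFilterBank("sym8", SYM8_H, n_vanishing_moments=8)
HAAR = WaveletFilterBank("haar", HAAR_H, n_vanishing_moments=1)

_BANKS = {"sym8": SYM8, "haar": HAAR}


def get_bank(name) -> WaveletFilterBank:
    if isinstance(name, WaveletFilterBank):
        return name
    try:
        return _BANKS[name]
    except KeyError:
        raise ValueError(f"unknown wavelet bank {name!r}; have {sorted(_BANKS)}")


_PYWT_MODE = {"periodic": "periodization", "symmetric": "symmetric"}


@dataclass
class MultilevelDecomposition:
    """Approximation + per-level detail coefficients.

    ``details[0]`` is level 1 (finest). Under the ``modwt`` scheme every
    sequence has length ``n_input``; under the decimated scheme lengths
    follow the boundary convention of the transform.
    """

    scheme: str                      # "decimated" | "modwt"
    bank_name: str
    levels: int
    approx: np.ndarray
    details: list = field(default_factory=list)
    boundary: str = "symmetric"      # "periodic" | "symmetric"
    n_input: int = 0

    def copy(self) -> "MultilevelDecomposition":
        return MultilevelDecomposition(
            scheme=self.scheme,
            bank_name=self.bank_name,
            levels=self.levels,
            approx=self.approx.copy(),
            details=[d.copy() for d in self.details],
            boundary=self.boundary,
            n_input=self.n_input,
        )


# ---------------------------------------------------------------------------
# Decimated transform (Mallat pyramid, via PyWavelets)

def _check_depth(n: int, J: int):
    if J < 1:
        raise ValueError("decomposition level J must be >= 1")
    if 2 ** J > n:
        raise ValueError(f"J={J} too deep for signal of length {n}")


def dwt_multilevel(x, bank="sym8", J: int = 4,
                   boundary: str = "symmetric") -> MultilevelDecomposition:
    """Decimated multilevel DWT (convolve-and-decimate by 2 per level)."""
    x = np.asarray(x, dtype=float)
    bank = get_bank(bank)
    _check_depth(len(x), J)
    if len(x) < len(bank.h):
        raise ValueError("signal shorter than the filter")
    with warnings.catch_warnings():
        # depth is already validated against our own precondition (2^J <= n)
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, bank.to_pywt(), mode=_PYWT_MODE[boundary], level=J)
    approx = coeffs[0]
    details = list(reversed(coeffs[1:]))  # level 1 first
    return MultilevelDecomposition(
        scheme="decimated", bank_name=bank.name, levels=J,
        approx=approx, details=details, boundary=boundary, n_input=len(x),
    )


def idwt_multilevel(d: MultilevelDecomposition, bank=None) -> np.ndarray:
    """Inverse of :func:`dwt_multilevel` (perfect reconstruction)."""
    bank = get_bank(bank if bank is not None else d.bank_name)
    if d.scheme != "decimated":
        raise ValueError("idwt_multilevel expects a decimated decomposition")
    if len(d.details) != d.levels:
        raise ValueError("decomposition structure inconsistent with its level count")
    coeffs = [d.approx] + list(reversed(d.details))
    y = pywt.waverec(coeffs, bank.to_pywt(), mode=_PYWT_MODE[d.boundary])
    return np.asarray(y[: d.n_input], dtype=float)


# ---------------------------------------------------------------------------
# MODWT (circular pyramid algorithm)

def _modwt_convolve(v: np.ndarray, taps: np.ndarray, step: int) -> np.ndarray:
    # out[t] = sum_l taps[l] * v[(t - step*l) mod N]; tap-ordered summation
    # keeps the transform bitwise shift-equivariant.
    out = taps[0] * v
    for l in range(1, len(taps)):
        out = out + taps[l] * np.roll(v, step * l)
    return out


def _modwt_convolve_adjoint(v: np.ndarray, taps: np.ndarray, step: int) -> np.ndarray:
    out = taps[0] * v
    for l in range(1, len(taps)):
        out = out + taps[l] * np.roll(v, -step * l)
    return out


def modwt(x, bank="sym8", J: int = 7) -> MultilevelDecomposition:
    """Maximal overlap (undecimated) DWT with circular boundary.

    Filters are rescaled by 2^(-1/2) per level and upsampled by 2^(j-1);
    every coefficient sequence keeps the input length and the transform is
    shift-equivariant and energy preserving.
    """
    x = np.asarray(x, dtype=float)
    bank = get_bank(bank)
    _check_depth(len(x), J)
    ht = bank.h / np.sqrt(2.0)
    gt = bank.g / np.sqrt(2.0)
    details = []
    v = x
    for j in range(1, J + 1):
        step = 2 ** (j - 1)
        details.append(_modwt_convolve(v, gt, step))
        v = _modwt_convolve(v, ht, step)
    return MultilevelDecomposition(
        scheme="modwt", bank_name=bank.name, levels=J,
        approx=v, details=details, boundary="periodic", n_input=len(x),
    )


def imodwt(d: MultilevelDecomposition, bank=None) -> np.ndarray:
    """Inverse MODWT (exact, circular)."""
    bank = get_bank(bank if bank is not None else d.bank_name)
    if d.scheme != "modwt":
        raise ValueError("imodwt expects a modwt decomposition")
    ht = bank.h / np.sqrt(2.0)
    gt = bank.g / np.sqrt(2.0)
    v = d.approx
    for j in range(d.levels, 0, -1):
        step = 2 ** (j - 1)
        v = (_modwt_convolve_adjoint(v, ht, step)
             + _modwt_convolve_adjoint(d.details[j - 1], gt, step))
    return v


# ---------------------------------------------------------------------------
# Multiresolution reconstruction and denoising

def mra_reconstruct(d: MultilevelDecomposition, keep_levels) -> np.ndarray:
    """Inverse transform with all coefficient sequences outside
    ``keep_levels`` zeroed.

    ``keep_levels`` is a set drawn from {1..J} plus the token ``"approx"``.
    By linearity the singleton reconstructions sum to the full inverse.
    """
    keep = set(keep_levels)
    if not keep:
        raise ValueError("keep_levels must not be empty")
    valid = set(range(1, d.levels + 1)) | {"approx"}
    if not keep <= valid:
        raise ValueError(f"keep_levels {keep - valid} outside {{1..J}} | {{'approx'}}")
    dd = d.copy()
    if "approx" not in keep:
        dd.approx = np.zeros_like(dd.approx)
    for j in range(1, d.levels + 1):
        if j not in keep:
            dd.details[j - 1] = np.zeros_like(dd.details[j - 1])
    if d.scheme == "modwt":
        return imodwt(dd)
    return idwt_multilevel(dd)


def universal_threshold(detail1: np.ndarray, n: int) -> float:
    """Donoho universal threshold sigma_hat * sqrt(2 ln n), with the noise
    scale estimated from the finest detail level by the MAD rule
    sigma_hat = median(|d1|) / 0.6745."""
    sigma = np.median(np.abs(detail1)) / 0.6745
    return float(sigma * np.sqrt(2.0 * np.log(max(n, 2))))


def denoise(x, bank="sym8", J: int = 4, rule: str = "soft",
            boundary: str = "symmetric") -> np.ndarray:
    """Wavelet shrinkage: soft-threshold all detail levels at the universal
    threshold, leave the approximation untouched, reconstruct."""
    x = np.asarray(x, dtype=float)
    if len(x) <= 2 ** J:
        raise ValueError(f"signal of length {len(x)} too short for J={J}")
    d = dwt_multilevel(x, bank=bank, J=J, boundary=boundary)
    thr = universal_threshold(d.details[0], len(x))
    if thr > 0:
        d.details = [pywt.threshold(w, thr, mode=rule) for w in d.details]
    return idwt_multilevel(d)


class WaveletDenoiser:
    """Stateless sklearn-style transformer applying :func:`denoise` per row.

    Operates on an (n_signals, n_samples) array; every signal (e.g. every
    lead of a record) is shrunk independently.
    """

    def __init__(self, wavelet: str = "sym8", level: int = 4, rule: str = "soft"):
        self.wavelet = wavelet
        self.level = level
        self.rule = rule

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([
            denoise(row, bank=self.wavelet, J=self.level, rule=self.rule)
            for row in X
        ])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"wavelet": self.wavelet, "level": self.level, "rule": self.rule}

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self
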
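"""Plentiful per-call feature extraction and common-feature filtering.

The classifiers downstream are deliberately fed a *large* bank of generic
time-series descriptors rather than a handful of hand-picked spectral
measurements; boosted trees then select what matters for each task. The bank
applies a registered set of per-series operators (distributional moments and
quantiles, autocorrelation and partial autocorrelation, autoregressive fits,
entropy and complexity measures, crossing/run statistics, stationarity
summaries, and Welch-spectrum summaries with band energies) to four views of
each call — the raw waveform, its first and second differences, and its
amplitude envelope — plus short-time spectrogram trajectory statistics and
wavelet band energies on the raw waveform. The full profile yields over 600
named features per call; a ``reduced`` profile keeps a fast ~150-feature
subset for large sweeps.

Operators that are undefined on a given call (e.g. spectral moments of a
silent call) return NaN instead of raising; the common-feature filter then
keeps exactly the features that are finite for *every* call of a dataset,
mirroring how a per-call-type analysis keeps only features shared by all
individuals' calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.fft import next_fast_len
from sklearn.base import BaseEstimator, TransformerMixin

from .core import CallRecord, FeatureMatrix, Waveform

MIN_SAMPLES = 64

_QUANTILES_FULL = (0.01, 0.05, 0.10, 0.20, 0.25, 0.30, 0.40, 0.60,
                   0.70, 0.75, 0.80, 0.90, 0.95, 0.99)
_QUANTILES_REDUCED = (0.05, 0.25, 0.75, 0.95)


@dataclass(frozen=True)
class FeatureVector:
    """Named feature values for one call (may contain NaN before filtering)."""

    values: dict[str, float]
    bank_version: str


def _acf(x: np.ndarray, nlags: int) -> np.ndarray:
    """Autocorrelation at lags 0..nlags via FFT; NaN for zero-variance input."""
    n = x.size
    xc = x - x.mean()
    var = np.dot(xc, xc) / n
    if var <= 0 or not np.isfinite(var):
        return np.full(nlags + 1, np.nan)
    nfft = next_fast_len(2 * n)
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f))[: nlags + 1] / n
    return acov / acov[0]


def _levinson(rho: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Durbin recursion on an autocorrelation sequence.

    Returns (pacf[1..order], AR coefficients of the final order, residual
    variance ratio sigma2/var(x)).
    """
    pacf = np.zeros(order)
    phi = np.zeros((order + 1, order + 1))
    sigma2 = 1.0
    for k in range(1, order + 1):
        num = rho[k] - np.dot(phi[k - 1, 1:k], rho[1:k][::-1])
        if sigma2 <= 0 or not np.isfinite(num):
            pacf[k - 1 :] = np.nan
            return pacf, np.full(order, np.nan), np.nan
        refl = num / sigma2
        phi[k, k] = refl
        phi[k, 1:k] = phi[k - 1, 1:k] - refl * phi[k - 1, 1:k][::-1]
        sigma2 *= 1.0 - refl**2
        pacf[k - 1] = refl
    return pacf, phi[order, 1 : order + 1], float(sigma2)


def _perm_entropy(x: np.ndarray, m: int) -> float:
    """Permutation entropy of order m, normalized to [0, 1]."""
    if x.size < m + 1:
        return np.nan
    windows = sliding_window_view(x, m)
    # the argsort permutation is a bijective code for each ordinal pattern
    ranks = np.argsort(windows, axis=1)
    codes = ranks @ (m ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / math.log(math.factorial(m)))


def _runs(mask: np.ndarray) -> int:
    """Longest run of True values."""
    if not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int(np.max(edges[1::2] - edges[0::2]))


def _hist_entropy(x: np.ndarray, bins: int) -> float:
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    if p.size <= 1:
        return 0.0
    return float(-np.sum(p * np.log(p)) / math.log(bins))


def _series_features(x: np.ndarray, rate: int, out: dict[str, float],
                     prefix: str, *, acf_lags: int, pacf_order: int,
                     ar_order: int, quantiles: tuple, reduced: bool) -> None:
    n = x.size
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = float(np.mean(x))
        sd = float(np.std(x))
        out[f"{prefix}_mean"] = mean
        out[f"{prefix}_sd"] = sd
        out[f"{prefix}_median"] = float(np.median(x))
        out[f"{prefix}_min"] = float(np.min(x))
        out[f"{prefix}_max"] = float(np.max(x))
        out[f"{prefix}_range"] = float(np.ptp(x))
        rms = float(np.sqrt(np.mean(x**2)))
        out[f"{prefix}_rms"] = rms
        med = float(np.median(x))
        out[f"{prefix}_mad"] = float(np.median(np.abs(x - med)))
        qvals = np.quantile(x, (0.25, 0.75) + tuple(quantiles))
        out[f"{prefix}_iqr"] = float(qvals[1] - qvals[0])
        z = (x - mean) / sd if sd > 0 else np.full(n, np.nan)
        out[f"{prefix}_skew"] = float(np.mean(z**3)) if sd > 0 else np.nan
        out[f"{prefix}_kurtosis"] = float(np.mean(z**4) - 3.0) if sd > 0 else np.nan
        out[f"{prefix}_cv"] = sd / abs(mean) if mean != 0 else np.nan
        out[f"{prefix}_crest"] = float(np.max(np.abs(x)) / rms) if rms > 0 else np.nan
        for q, v in zip(quantiles, qvals[2:]):
            out[f"{prefix}_q{int(round(q * 100)):02d}"] = float(v)

        rho = _acf(x, acf_lags)
        for lag in range(1, acf_lags + 1):
            out[f"{prefix}_acf_lag{lag:02d}"] = float(rho[lag])
        finite_rho = rho[1:]
        neg = np.flatnonzero(finite_rho < 0)
        out[f"{prefix}_acf_first_zero"] = float(neg[0] + 1) if neg.size else np.nan
        if np.all(np.isfinite(finite_rho)):
            mins = np.flatnonzero(np.diff(finite_rho) > 0)
            out[f"{prefix}_acf_first_min"] = float(mins[0] + 1) if mins.size else np.nan
            out[f"{prefix}_acf_sumsq"] = float(
                np.sum(finite_rho[: min(20, acf_lags)] ** 2))
        else:
            out[f"{prefix}_acf_first_min"] = np.nan
            out[f"{prefix}_acf_sumsq"] = np.nan

        if not reduced:
            pacf, ar_coef, ar_sigma2 = (
                _levinson(rho, max(pacf_order, ar_order))
                if np.all(np.isfinite(rho[: max(pacf_order, ar_order) + 1]))
                else (np.full(pacf_order, np.nan), np.full(ar_order, np.nan), np.nan)
            )
            for k in range(1, pacf_order + 1):
                out[f"{prefix}_pacf_lag{k:02d}"] = float(pacf[k - 1])
            _, ar_final, ar_sigma2 = (
                _levinson(rho, ar_order)
                if np.all(np.isfinite(rho[: ar_order + 1]))
                else (None, np.full(ar_order, np.nan), np.nan)
            )
            for k in range(ar_order):
                out[f"{prefix}_ar{ar_order}_c{k + 1}"] = float(ar_final[k])
            out[f"{prefix}_ar{ar_order}_sigma2"] = float(ar_sigma2)

        # Hjorth parameters
        dx = np.diff(x)
        ddx = np.diff(dx)
        v0, v1, v2 = np.var(x), np.var(dx), np.var(ddx)
        mob = math.sqrt(v1 / v0) if v0 > 0 else np.nan
        out[f"{prefix}_hjorth_mobility"] = mob
        out[f"{prefix}_hjorth_complexity"] = (
            math.sqrt(v2 / v1) / mob if v1 > 0 and mob and mob > 0 else np.nan
        )

        out[f"{prefix}_zero_cross_rate"] = float(
            np.mean(np.signbit(x[:-1]) != np.signbit(x[1:])))
        above = x > mean
        out[f"{prefix}_mean_cross_rate"] = float(np.mean(above[:-1] != above[1:]))
        out[f"{prefix}_longest_above_mean"] = _runs(above) / n
        out[f"{prefix}_longest_below_mean"] = _runs(~above) / n
        out[f"{prefix}_local_max_rate"] = float(
            np.mean((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])))

        out[f"{prefix}_hist_entropy_10"] = _hist_entropy(x, 10)
        if not reduced:
            out[f"{prefix}_hist_entropy_32"] = _hist_entropy(x, 32)
        for m in (3, 4, 5) if not reduced else (3,):
            out[f"{prefix}_perm_entropy_m{m}"] = _perm_entropy(x, m)

        if not reduced:
            for lag in (1, 2, 3):
                if n > 2 * lag:
                    out[f"{prefix}_c3_lag{lag}"] = float(
                        np.mean(x[2 * lag :] * x[lag:-lag] * x[: -2 * lag]))
                    d = x[lag:] - x[:-lag]
                    m2 = np.mean(d**2)
                    out[f"{prefix}_trev_lag{lag}"] = (
                        float(np.mean(d**3) / m2**1.5) if m2 > 0 else np.nan)
                else:
                    out[f"{prefix}_c3_lag{lag}"] = np.nan
                    out[f"{prefix}_trev_lag{lag}"] = np.nan
        out[f"{prefix}_cid_ce"] = (
            float(np.sqrt(np.sum(dx**2)) / (sd * math.sqrt(n))) if sd > 0 else np.nan)

        # stationarity: variability of segment means/sds relative to global
        for nseg in (5, 10) if not reduced else (5,):
            if n >= nseg * 4:
                segs = np.array_split(x, nseg)
                seg_means = np.array([s.mean() for s in segs])
                seg_sds = np.array([s.std() for s in segs])
                out[f"{prefix}_statav_{nseg}"] = (
                    float(seg_means.std() / sd) if sd > 0 else np.nan)
                out[f"{prefix}_segsd_ratio_{nseg}"] = (
                    float(seg_sds.std() / sd) if sd > 0 else np.nan)
            else:
                out[f"{prefix}_statav_{nseg}"] = np.nan
                out[f"{prefix}_segsd_ratio_{nseg}"] = np.nan

        t = np.arange(n) / rate
        if sd > 0:
            slope, intercept = np.polyfit(t, x, 1)
            resid = x - (slope * t + intercept)
            out[f"{prefix}_trend_slope"] = float(slope)
            out[f"{prefix}_trend_r2"] = float(1.0 - np.var(resid) / v0)
        else:
            out[f"{prefix}_trend_slope"] = 0.0
            out[f"{prefix}_trend_r2"] = np.nan


def _spectral_features(x: np.ndarray, rate: int, out: dict[str, float],
                       prefix: str, *, n_bands: int, reduced: bool) -> None:
    n = x.size
    nperseg = min(4096, n)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.welch(x, fs=rate, nperseg=nperseg)
        total = p.sum()
        if total <= 0 or not np.isfinite(total):
            names = (["centroid", "spread", "skew", "kurtosis", "flatness",
                      "entropy", "crest", "peak_freq", "peak_frac"]
                     + [f"rolloff_{int(q * 100)}" for q in
                        ((0.25, 0.5, 0.75, 0.95) if reduced
                         else (0.05, 0.25, 0.5, 0.75, 0.85, 0.95))]
                     + [f"band_{b:02d}" for b in range(n_bands)])
            for name in names:
                out[f"{prefix}_spec_{name}"] = np.nan
            return
        pn = p / total
        centroid = float(np.sum(f * pn))
        spread = float(np.sqrt(np.sum((f - centroid) ** 2 * pn)))
        out[f"{prefix}_spec_centroid"] = centroid
        out[f"{prefix}_spec_spread"] = spread
        if spread > 0:
            out[f"{prefix}_spec_skew"] = float(
                np.sum(((f - centroid) / spread) ** 3 * pn))
            out[f"{prefix}_spec_kurtosis"] = float(
                np.sum(((f - centroid) / spread) ** 4 * pn) - 3.0)
        else:
            out[f"{prefix}_spec_skew"] = np.nan
            out[f"{prefix}_spec_kurtosis"] = np.nan
        pos = p[p > 0]
        out[f"{prefix}_spec_flatness"] = float(
            np.exp(np.mean(np.log(pos))) / np.mean(p)) if pos.size else np.nan
        pn_pos = pn[pn > 0]
        out[f"{prefix}_spec_entropy"] = float(
            -np.sum(pn_pos * np.log(pn_pos)) / math.log(pn.size))
        out[f"{prefix}_spec_crest"] = float(np.max(p) / np.mean(p))
        cum = np.cumsum(pn)
        for q in (0.25, 0.5, 0.75, 0.95) if reduced else (0.05, 0.25, 0.5,
                                                          0.75, 0.85, 0.95):
            out[f"{prefix}_spec_rolloff_{int(q * 100)}"] = float(
                f[np.searchsorted(cum, q)])
        peak = int(np.argmax(p))
        out[f"{prefix}_spec_peak_freq"] = float(f[peak])
        out[f"{prefix}_spec_peak_frac"] = float(pn[peak])
        edges = np.linspace(0, rate / 2, n_bands + 1)
        idx = np.clip(np.digitize(f, edges) - 1, 0, n_bands - 1)
        band = np.bincount(idx, weights=pn, minlength=n_bands)
        for b in range(n_bands):
            out[f"{prefix}_spec_band_{b:02d}"] = float(band[b])


def _spectrogram_features(x: np.ndarray, rate: int, out: dict[str, float]) -> None:
    """Short-time trajectory statistics: Hann window 512, hop 256 (scaled
    down for very short calls)."""
    n = x.size
    nperseg = min(512, 2 ** int(math.log2(max(n // 4, 16))))
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, t, z = sps.stft(x, fs=rate, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2)
        p = np.abs(z) ** 2
        frame_power = p.sum(axis=0)
        valid = frame_power > 1e-12 * frame_power.max() if frame_power.max() > 0 else \
            np.zeros_like(frame_power, dtype=bool)
        names = ["flux_mean", "flux_sd", "flux_max", "centroid_t_mean",
                 "centroid_t_sd", "centroid_t_slope", "bw_t_mean", "bw_t_sd",
                 "peak_t_mean", "peak_t_sd", "peak_t_slope"]
        if valid.sum() < 3:
            for name in names:
                out[f"stft_{name}"] = np.nan
            return
        pv = p[:, valid]
        tv = t[valid]
        pn = pv / pv.sum(axis=0, keepdims=True)
        cen = (f[:, None] * pn).sum(axis=0)
        bw = np.sqrt((((f[:, None] - cen[None, :]) ** 2) * pn).sum(axis=0))
        peak = f[np.argmax(pv, axis=0)]
        flux = np.sqrt(((np.diff(pn, axis=1)) ** 2).sum(axis=0))
        out["stft_flux_mean"] = float(flux.mean())
        out["stft_flux_sd"] = float(flux.std())
        out["stft_flux_max"] = float(flux.max())
        out["stft_centroid_t_mean"] = float(cen.mean())
        out["stft_centroid_t_sd"] = float(cen.std())
        out["stft_centroid_t_slope"] = float(np.polyfit(tv, cen, 1)[0])
        out["stft_bw_t_mean"] = float(bw.mean())
        out["stft_bw_t_sd"] = float(bw.std())
        out["stft_peak_t_mean"] = float(peak.mean())
        out["stft_peak_t_sd"] = float(peak.std())
        out["stft_peak_t_slope"] = float(np.polyfit(tv, peak, 1)[0])


def _wavelet_features(x: np.ndarray, out: dict[str, float], max_level: int = 7) -> None:
    with np.errstate(all="ignore"):
        level = min(max_level, pywt.dwt_max_level(x.size, "db4"))
        energies = np.full(max_level + 1, np.nan)
        if level >= 1:
            coeffs = pywt.wavedec(x, "db4", level=level)
            e = np.array([float(np.sum(c**2)) for c in coeffs])
            total = e.sum()
            if total > 0:
                energies[: level + 1] = e / total
        for i in range(max_level + 1):
            out[f"wav_energy_l{i}"] = float(energies[i])
        pos = energies[np.isfinite(energies) & (energies > 0)]
        out["wav_entropy"] = (
            float(-np.sum(pos * np.log(pos))) if pos.size else np.nan)


class FeatureBank:
    """A registered, versioned bank of per-call acoustic features.

    ``profile='full'`` applies the whole operator set to all four views
    (>600 features); ``profile='reduced'`` keeps a fast subset on the raw
    waveform and envelope (~150 features) for large experiments.
    """

    VERSION = "1.0"

    def __init__(self, profile: str = "full"):
        if profile not in ("full", "reduced"):
            raise ValueError(f"unknown bank profile {profile!r}")
        self.profile = profile
        self._reduced = profile == "reduced"
        self.views = ("signal", "envelope") if self._reduced else (
            "signal", "diff1", "diff2", "envelope")
        self.acf_lags = 10 if self._reduced else 40
        self.pacf_order = 15
        self.ar_order = 8
        self.n_bands = 16
        self.quantiles = _QUANTILES_REDUCED if self._reduced else _QUANTILES_FULL
        self._names: list[str] | None = None

    @property
    def bank_version(self) -> str:
        return f"hievox-bank-{self.VERSION}-{self.profile}"

    def feature_names(self) -> list[str]:
        """Registered feature names, in extraction order."""
        if self._names is None:
            rng = np.random.default_rng(0)
            dummy = Waveform(samples=np.clip(rng.normal(0, 0.1, 2048), -1, 1),
                             rate_hz=62_500)
            self._names = list(self.extract(dummy).values)
        return list(self._names)

    def extract(self, w: Waveform) -> FeatureVector:
        """Extract the full bank from one call. Deterministic; operators
        that fail on this call yield NaN."""
        x = w.samples
        if x.size < MIN_SAMPLES:
            raise ValueError(
                f"waveform has {x.size} samples; at least {MIN_SAMPLES} are "
                "required for the analysis windows")
        out: dict[str, float] = {}
        env = np.abs(sps.hilbert(x, N=next_fast_len(x.size))[: x.size])
        view_data = {
            "signal": x,
            "diff1": np.diff(x),
            "diff2": np.diff(x, 2),
            "envelope": env,
        }
        out["duration_s"] = w.duration_s
        for view in self.views:
            xv = view_data[view]
            _series_features(xv, w.rate_hz, out, view,
                             acf_lags=self.acf_lags, pacf_order=self.pacf_order,
                             ar_order=self.ar_order, quantiles=self.quantiles,
                             reduced=self._reduced)
            _spectral_features(xv, w.rate_hz, out, view,
                               n_bands=self.n_bands, reduced=self._reduced)
        _spectrogram_features(x, w.rate_hz, out)
        if not self._reduced:
            _wavelet_features(x, out)
        return FeatureVector(values=out, bank_version=self.bank_version)


_DEFAULT_BANK: dict[str, FeatureBank] = {}


def get_bank(profile: str = "full") -> FeatureBank:
    if profile not in _DEFAULT_BANK:
        _DEFAULT_BANK[profile] = FeatureBank(profile)
    return _DEFAULT_BANK[profile]


def extract_feature_vector(w: Waveform, bank: FeatureBank | None = None) -> FeatureVector:
    """Extract the registered feature bank from one waveform."""
    return (bank or get_bank()).extract(w)


def build_feature_matrix(
    waveforms: list[Waveform],
    records: list[CallRecord],
    bank: FeatureBank | None = None,
) -> FeatureMatrix:
    """Extract features for a per-call-type dataset, rows in record order.

    All records must share one call type (datasets are built per type);
    the matrix is *not* yet common-feature filtered.
    """
    bank = bank or get_bank()
    if len(waveforms) != len(records):
        raise ValueError(
            f"{len(waveforms)} waveforms for {len(records)} records")
    if not records:
        raise ValueError("no records given")
    types = {r.call_type for r in records}
    if len(types) > 1:
        raise ValueError(
            f"mixed call types {sorted(types)}: build one matrix per call type")
    rows, index = [], []
    for w, r in zip(waveforms, records):
        if w is None:
            raise ValueError(f"record {r.call_id!r} has no waveform")
        rows.append(bank.extract(w).values)
        index.append(r.call_id)
    values = pd.DataFrame(rows, index=pd.Index(index, name="call_id"))
    labels = pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "sex": [r.sex for r in records],
            "call_type": [r.call_type for r in records],
        },
        index=values.index,
    )
    return FeatureMatrix(values=values, labels=labels,
                         bank_version=bank.bank_version,
                         provenance={"n_calls": len(records)})


def filter_common_features(m: FeatureMatrix) -> FeatureMatrix:
    """Keep exactly the features finite for every call; order preserved.

    The dropped feature names are recorded in the matrix provenance.
    """
    if m.n_calls == 0:
        raise ValueError("empty feature matrix")
    finite = np.isfinite(m.values.to_numpy()).all(axis=0)
    kept = [name for name, ok in zip(m.feature_names, finite) if ok]
    dropped = [name for name, ok in zip(m.feature_names, finite) if not ok]
    if not kept:
        raise ValueError("no feature is finite across all calls")
    provenance = dict(m.provenance)
    provenance["common_feature_filter"] = {
        "n_kept": len(kept),
        "n_dropped": len(dropped),
        "dropped": dropped,
    }
    return FeatureMatrix(values=m.values[kept], labels=m.labels,
                         bank_version=m.bank_version, provenance=provenance)


class CommonFeatureFilter(BaseEstimator, TransformerMixin):
    """sklearn transformer form of the common-feature filter.

    ``fit`` learns which columns are finite on every training call;
    ``transform`` subsets to them.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        finite = np.isfinite(X.to_numpy()).all(axis=0)
        self.kept_features_ = [c for c, ok in zip(X.columns, finite) if ok]
        self.dropped_features_ = [c for c, ok in zip(X.columns, finite) if not ok]
        if not self.kept_features_:
            raise ValueError("no feature is finite across all calls")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.kept_features_]
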
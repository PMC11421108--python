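"""Synthetic inputs: audio days with click trains, tuning corpora, reference series, SST grids.

Everything downstream of raw data acquisition is testable from this module
alone.  Audio days are colored-noise waveforms at 16 kHz carrying band-limited
impulse trains with near-constant inter-click intervals; negative days may
carry irregularly timed impulsive transients so that the interval filter, not
the energy detector, is what rejects them.  Reference monthly-presence
fixtures are anchored to the printed southern-station extrema (59.3% of days
in January, 31.1% in July); the northern fixture is opposite in phase.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from deepclick.clickdetect import round_quarter

__all__ = [
    "ClickTrainSpec",
    "LabeledDay",
    "gen_click_train",
    "gen_audio_day",
    "render_waveform",
    "gen_labeled_corpus",
    "gen_reference_series",
    "default_reference_table",
    "gen_sst_grid",
    "SOUTH_PEAK_PERCENT",
    "SOUTH_TROUGH_PERCENT",
]

#: Printed southern-station anchors: January mean and July mean percent of days present.
SOUTH_PEAK_PERCENT = 59.3
SOUTH_TROUGH_PERCENT = 31.1

#: Detector band used as the SNR reference for click scaling (Hz).
_SNR_BAND = (1400.0, 4000.0)
#: Click carrier frequency (Hz): the detector's center frequency.
_CLICK_FC = 2700.0
#: Repetition threshold defining a qualifying train for day-level truth labels.
_QUALIFYING_R = 6

_SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class ClickTrainSpec:
    """One regular echolocation click train within a recording day.

    ``ici_jitter_sd`` is the standard deviation of successive intervals
    around ``ici_mean``; ``snr_db`` is the short-time in-band energy of each
    click above the background band level.
    """

    start_time: float
    n_clicks: int
    ici_mean: float
    ici_jitter_sd: float = 0.0
    click_duration: float = 0.010
    snr_db: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.ici_mean <= 10.0:
            raise ValueError(f"ici_mean must be in (0, 10], got {self.ici_mean}")
        if self.ici_jitter_sd < 0:
            raise ValueError(f"ici_jitter_sd must be >= 0, got {self.ici_jitter_sd}")
        if self.n_clicks < 2:
            raise ValueError(f"n_clicks must be >= 2, got {self.n_clicks}")
        if self.start_time < 0:
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")
        if self.click_duration <= 0:
            raise ValueError(f"click_duration must be > 0, got {self.click_duration}")
        if self.start_time + self.n_clicks * self.ici_mean > _SECONDS_PER_DAY:
            raise ValueError("start_time + n_clicks * ici_mean exceeds the 86400 s day")


@dataclass
class LabeledDay:
    """A (possibly lazily rendered) synthetic recording day with ground truth.

    ``truth_present`` is true iff at least one train has ``n_clicks >= r + 1``
    (r = 6) and a rounded mean ICI within [0.5, 2.0] s.  ``waveform`` may be
    None for corpora generated lazily; call :meth:`render` to synthesize it
    reproducibly from ``day_seed``.
    """

    day_id: dt.date
    truth_present: bool
    truth_trains: list[ClickTrainSpec]
    waveform: np.ndarray | None = None
    fs: float = 16000.0
    day_length_s: float = 600.0
    noise_spectrum_level: float = -40.0
    day_seed: int = 0
    transient_times: np.ndarray = field(default_factory=lambda: np.array([]))
    transient_snr_db: float = 20.0

    def render(self) -> np.ndarray:
        """Synthesize (and cache) the waveform for this day."""
        self.waveform = render_waveform(self)
        return self.waveform


def _qualifies(train: ClickTrainSpec, r: int = _QUALIFYING_R) -> bool:
    return train.n_clicks >= r + 1 and 0.5 <= round_quarter(train.ici_mean) <= 2.0


def gen_click_train(spec: ClickTrainSpec, rng_seed: int) -> np.ndarray:
    """Click onset times (s) for one train.

    Successive intervals are ``ici_mean + Normal(0, ici_jitter_sd)``,
    truncated so every interval is positive.  When ``ici_jitter_sd <= 0.1``
    the deviations are additionally truncated to stay inside the quarter-second
    rounding bin of ``ici_mean``, so every rounded interval equals
    ``round_quarter(ici_mean)`` — the jitter models within-train variability
    of a regular but not exactly constant click train.
    """
    rng = np.random.default_rng(rng_seed)
    n_iv = spec.n_clicks - 1
    if spec.ici_jitter_sd == 0:
        intervals = np.full(n_iv, spec.ici_mean)
    else:
        if spec.ici_jitter_sd <= 0.1:
            rq = round_quarter(spec.ici_mean)
            lo = max(1e-6, rq - 0.124) - spec.ici_mean
            hi = (rq + 0.124) - spec.ici_mean
        else:
            lo, hi = -spec.ici_mean + 1e-6, np.inf
        dev = rng.normal(0.0, spec.ici_jitter_sd, n_iv)
        for _ in range(1000):
            bad = (dev <= lo) | (dev >= hi)
            if not bad.any():
                break
            dev[bad] = rng.normal(0.0, spec.ici_jitter_sd, int(bad.sum()))
        dev = np.clip(dev, lo + 1e-9, hi - 1e-9)
        intervals = spec.ici_mean + dev
    return spec.start_time + np.concatenate([[0.0], np.cumsum(intervals)])


def _gabor_click(duration: float, fs: float) -> np.ndarray:
    """Unit-amplitude band-limited impulse: Gaussian-windowed tone at 2.7 kHz."""
    n = max(8, int(round(duration * fs)))
    t = (np.arange(n) - (n - 1) / 2) / fs
    tau = duration / 6.0
    return np.exp(-0.5 * (t / tau) ** 2) * np.sin(2 * np.pi * _CLICK_FC * t)


def _click_window_ms(click: np.ndarray, fs: float, window: float = 0.010) -> float:
    """Peak short-time mean-square of a click over a sliding analysis window."""
    win_n = int(round(window * fs))
    sq = np.concatenate([[0.0], np.cumsum(click * click)])
    if click.size <= win_n:
        return float(sq[-1] / win_n)
    tot = sq[win_n:] - sq[: -win_n]
    return float(tot.max() / win_n)


def _noise_band_ms(noise_spectrum_level: float) -> float:
    """In-band mean square of flat-spectrum noise at the given spectral level (dB)."""
    return 10.0 ** (noise_spectrum_level / 10.0) * (_SNR_BAND[1] - _SNR_BAND[0])


def _add_impulse(
    wav: np.ndarray, t0: float, duration: float, snr_db: float, noise_spectrum_level: float, fs: float
) -> None:
    g = _gabor_click(duration, fs)
    target_ms = _noise_band_ms(noise_spectrum_level) * 10.0 ** (snr_db / 10.0)
    amp = np.sqrt(target_ms / _click_window_ms(g, fs))
    i0 = int(round(t0 * fs))
    i1 = min(i0 + g.size, wav.size)
    if i0 < wav.size:
        wav[i0:i1] += amp * g[: i1 - i0]


def render_waveform(day: LabeledDay) -> np.ndarray:
    """Colored noise + rendered click trains (+ transients) for one labeled day."""
    rng = np.random.default_rng(day.day_seed)
    n = int(round(day.day_length_s * day.fs))
    sigma = np.sqrt(10.0 ** (day.noise_spectrum_level / 10.0) * day.fs / 2.0)
    wav = sigma * rng.standard_normal(n)
    for k, spec in enumerate(day.truth_trains):
        times = gen_click_train(spec, rng_seed=int(day.day_seed + 7919 * (k + 1)) % 2**31)
        for t0 in times:
            if t0 + spec.click_duration < day.day_length_s:
                _add_impulse(wav, t0, spec.click_duration, spec.snr_db, day.noise_spectrum_level, day.fs)
    for t0 in np.asarray(day.transient_times, dtype=float):
        if t0 + 0.010 < day.day_length_s:
            _add_impulse(wav, t0, 0.010, day.transient_snr_db, day.noise_spectrum_level, day.fs)
    return wav


def gen_audio_day(
    trains: list[ClickTrainSpec],
    noise_spectrum_level: float = -40.0,
    fs: float = 16000.0,
    day_length_s: float = _SECONDS_PER_DAY,
    rng_seed: int = 0,
    day_id: dt.date = dt.date(2016, 1, 1),
    transient_times: np.ndarray | None = None,
    transient_snr_db: float = 20.0,
) -> LabeledDay:
    """Render one labeled audio day: noise plus each train's band-limited impulses.

    Each click is scaled so its short-time in-band energy exceeds the noise
    band level by the train's ``snr_db``.  Trains need not be disjoint.
    """
    for spec in trains:
        if spec.start_time + spec.n_clicks * spec.ici_mean > day_length_s:
            raise ValueError(
                f"train at start_time={spec.start_time} does not fit in a {day_length_s} s day"
            )
    day = LabeledDay(
        day_id=day_id,
        truth_present=any(_qualifies(s) for s in trains),
        truth_trains=list(trains),
        fs=fs,
        day_length_s=day_length_s,
        noise_spectrum_level=noise_spectrum_level,
        day_seed=int(rng_seed) % 2**31,
        transient_times=np.array([] if transient_times is None else transient_times, dtype=float),
        transient_snr_db=transient_snr_db,
    )
    day.render()
    return day


def gen_labeled_corpus(
    n_days: int = 50,
    prevalence: float = 0.5,
    snr_range: tuple[float, float] = (6.0, 20.0),
    rng_seed: int = 0,
    day_length_s: float = 600.0,
    fs: float = 16000.0,
    noise_spectrum_level: float = -40.0,
    transient_rate_per_s: float = 0.03,
    render: bool = False,
    start_date: dt.date = dt.date(2016, 1, 1),
) -> list[LabeledDay]:
    """A labeled tuning corpus emulating a manually assessed validation set.

    Exactly ``round(prevalence * n_days)`` days are positive, carrying 1-5
    regular trains (>= 7 clicks, mean ICI uniform on [0.5, 2.0] s, SNR uniform
    on ``snr_range``).  Negative days carry Poisson-timed impulsive transients
    with irregular intervals — confounders that the energy detector flags but
    the interval filter must reject.  Waveforms are rendered lazily unless
    ``render=True``; each day synthesizes reproducibly from its own seed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_pos = int(round(prevalence * n_days))
    is_pos = np.zeros(n_days, dtype=bool)
    is_pos[rng.permutation(n_days)[:n_pos]] = True

    days: list[LabeledDay] = []
    for i in range(n_days):
        day_seed = int(rng.integers(2**31))
        day_rng = np.random.default_rng(day_seed + 1)
        trains: list[ClickTrainSpec] = []
        transients = np.array([])
        if is_pos[i]:
            # some whales pass briefly: ~30% of positive days hold a single
            # minimal train (7-8 clicks), so over-conservative r loses recall
            minimal = day_rng.uniform() < 0.3
            n_trains = 1 if minimal else int(day_rng.integers(1, 6))
            for _ in range(n_trains):
                ici = float(day_rng.uniform(0.5, 2.0))
                max_clicks = min(40, int((day_length_s / 2) / ici))
                if minimal:
                    n_clicks = int(day_rng.integers(7, 9))
                else:
                    n_clicks = int(day_rng.integers(7, max(8, max_clicks + 1)))
                dur = n_clicks * ici
                start = float(day_rng.uniform(5.0, day_length_s - dur - 5.0))
                trains.append(
                    ClickTrainSpec(
                        start_time=start,
                        n_clicks=n_clicks,
                        ici_mean=ici,
                        ici_jitter_sd=float(day_rng.uniform(0.0, 0.08)),
                        snr_db=float(day_rng.uniform(*snr_range)),
                    )
                )
        else:
            n_tr = day_rng.poisson(transient_rate_per_s * day_length_s)
            transients = np.sort(day_rng.uniform(0.0, day_length_s - 1.0, n_tr))
        day = LabeledDay(
            day_id=start_date + dt.timedelta(days=i),
            truth_present=bool(is_pos[i]) and any(_qualifies(s) for s in trains),
            truth_trains=trains,
            fs=fs,
            day_length_s=day_length_s,
            noise_spectrum_level=noise_spectrum_level,
            day_seed=day_seed,
            transient_times=transients,
            transient_snr_db=float(day_rng.uniform(*snr_range)),
        )
        if render:
            day.render()
        days.append(day)
    return days


def gen_reference_series(
    peak_percent: float = SOUTH_PEAK_PERCENT,
    trough_percent: float = SOUTH_TROUGH_PERCENT,
    station_id: str = "south",
    peak_month: int = 1,
) -> pd.DataFrame:
    """Smooth 12-month sinusoid of percent of days present.

    The series takes ``peak_percent`` at ``peak_month`` and ``trough_percent``
    six months later.  Defaults reproduce the southern-station anchors (59.3%
    in January, 31.1% in July).
    """
    if not 0 <= trough_percent <= peak_percent <= 100:
        raise ValueError("need 0 <= trough_percent <= peak_percent <= 100")
    if not 1 <= peak_month <= 12:
        raise ValueError("peak_month must be in 1..12")
    months = np.arange(1, 13)
    mid = (peak_percent + trough_percent) / 2.0
    amp = (peak_percent - trough_percent) / 2.0
    vals = mid + amp * np.cos(2 * np.pi * (months - peak_month) / 12.0)
    return pd.DataFrame(
        {"station_id": station_id, "month": months, "mean_percent_present": vals}
    )


def default_reference_table(
    north_peak: float = 85.0, north_trough: float = 20.0
) -> pd.DataFrame:
    """12 x 2 reference table (index month, columns south/north percent present).

    South is the printed winter-peaked series; north is opposite in phase with
    a stronger summer peak, emulating high-latitude seasonality.
    """
    south = gen_reference_series()
    north = gen_reference_series(north_peak, north_trough, "north", peak_month=7)
    table = pd.concat([south, north]).pivot(
        index="month", columns="station_id", values="mean_percent_present"
    )
    return table[["south", "north"]]


def gen_sst_grid(
    iso18_lat: float = 40.0,
    meridional_gradient: float = -0.5,
    noise_sd: float = 0.0,
    lons: np.ndarray | None = None,
    lats: np.ndarray | None = None,
    rng_seed: int = 0,
    month: int = 1,
) -> xr.DataArray:
    """Gridded SST (degC) with a controllable 18 degC isotherm latitude.

    ``sst(lat, lon) = 18 + meridional_gradient * (lat - iso18_lat) + N(0, noise_sd)``.
    Longitudes default to the 160-180 degW window in 0-360 convention.
    """
    if lats is None:
        lats = np.arange(25.0, 55.25, 0.25)
    if lons is None:
        lons = np.arange(180.0, 200.5, 0.5)
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if meridional_gradient >= 0:
        raise ValueError("meridional_gradient must be < 0 (SST decreases northward)")
    if not lats.min() <= iso18_lat <= lats.max():
        raise ValueError(f"iso18_lat {iso18_lat} outside grid range [{lats.min()}, {lats.max()}]")
    rng = np.random.default_rng(rng_seed)
    sst = 18.0 + meridional_gradient * (lats[:, None] - iso18_lat) + rng.normal(
        0.0, noise_sd, (lats.size, lons.size)
    ) if noise_sd > 0 else 18.0 + meridional_gradient * (lats[:, None] - iso18_lat) * np.ones(
        (1, lons.size)
    )
    return xr.DataArray(
        sst, coords={"lat": lats, "lon": lons}, dims=("lat", "lon"), name="sst", attrs={"month": month}
    )
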
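"""Seeded generative model of lickometry sessions and cohorts.

Sessions are built from three ingredients:

* **Bout anchors** from a piecewise-constant-intensity Poisson process over
  session time.  The segment edges (0-30, 30-120, 120-150, 150-240 min)
  match the frontloading and late-session analysis windows, so phenotypes
  can concentrate drinking early (frontloading) or late in long sessions.
* **Bout contents**: each bout gets a shifted-geometric number of licks
  (minimum 1) with within-bout inter-lick intervals drawn from a gamma
  truncated at the bout-initiation ILI ceiling — every generated bout of
  three or more licks therefore satisfies the detection criteria by
  construction — and contact durations from a lognormal.
* **Isolated (non-bout) licks** from a homogeneous Poisson process, placed
  uniformly and rejected if they fall within the bout-termination gap of any
  existing lick, so they can neither join nor seed a detectable bout.

Bouts are spaced more than the termination gap apart (colliding anchors are
dropped), which makes bout recovery by the segmentation module exact for
every generated bout of size >= 3.

Two genotype presets encode the contrast between control mice and mice
lacking peripheral alcohol dehydrogenase (ADH1): the knockout preset has a
lower bout rate, smaller bouts, twice the non-bout contact duration, twice
the blood-ethanol accumulation slope, and an elevated bout rate in the
120-150 min window of long sessions; isolated-lick rates are identical
across presets.  Only those ratios and orderings are anchored to reported
phenotypes; the absolute values are declared defaults (see the constants
below and the methods note).

Intake is derived from the lick train (licks x volume per lick) and written
back as bottle masses, so the manifest inverts the intake conversion
exactly when noise is disabled.  Blood ethanol concentration at session end
is linear in intake with genotype-dependent slope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bout_segmentation import SegmentationParams
from .errors import ValidationError
from .event_io import SessionRecord
from .intake_pk import FluidSpec, compute_intake
from .lick_processing import Lick

_log = logging.getLogger(__name__)

#: Session-time segment edges, seconds (0-30, 30-120, 120-150, 150-240 min).
SEGMENT_EDGES = (0.0, 1800.0, 7200.0, 9000.0, 14400.0)

#: Margin added to the termination gap when spacing bouts / isolated licks,
#: so boundary comparisons can never flip membership (seconds).
_SPACING_MARGIN = 0.5


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal by median and log-space sigma (so median ratios are exact)."""

    median: float
    sigma: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.median * np.exp(self.sigma * rng.standard_normal(size))

    @property
    def mean(self) -> float:
        return self.median * math.exp(self.sigma**2 / 2)


@dataclass(frozen=True)
class GammaSpec:
    """Gamma by mean and shape."""

    mean: float
    shape: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.gamma(self.shape, self.mean / self.shape, size)


@dataclass(frozen=True)
class PiecewiseRate:
    """Piecewise-constant event rate (per hour) over session-time segments."""

    edges: tuple[float, ...] = SEGMENT_EDGES
    rates_per_hour: tuple[float, ...] = (0.0,)

    def __post_init__(self):
        if len(self.edges) != len(self.rates_per_hour) + 1:
            raise ValidationError("need len(edges) == len(rates) + 1")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValidationError("segment edges must be increasing")
        if any(r < 0 for r in self.rates_per_hour):
            raise ValidationError("rates must be >= 0")

    def segments_within(self, t_end: float) -> list[tuple[float, float, float]]:
        """(start, end, rate/h) triples clipped to [0, t_end)."""
        out = []
        for a, b, r in zip(self.edges, self.edges[1:], self.rates_per_hour):
            lo, hi = max(a, 0.0), min(b, t_end)
            if hi > lo:
                out.append((lo, hi, r))
        return out


@dataclass(frozen=True)
class PhenotypeParams:
    """Generator parameters for one genotype preset."""

    bout_rate: PiecewiseRate
    bout_size_mean: float
    within_ili: GammaSpec
    bout_lick_duration: LognormalSpec
    isolated_lick_rate: float  # licks per hour
    nonbout_lick_duration: LognormalSpec
    volume_per_lick: tuple[float, float]  # microliters (mean, sd)
    bec_slope: float  # concentration units per (g/kg)
    bec_noise_sd: float
    intake_noise_sd: float  # g/kg

    def __post_init__(self):
        if self.bout_size_mean < 1:
            raise ValidationError("bout_size_mean must be >= 1")
        if self.isolated_lick_rate < 0:
            raise ValidationError("isolated_lick_rate must be >= 0")
        if self.volume_per_lick[0] <= 0 or self.volume_per_lick[1] < 0:
            raise ValidationError("volume_per_lick mean must be > 0, sd >= 0")


# Declared default presets.  Only the following features are anchored to the
# reported knockout phenotype: KO/WT non-bout duration median ratio = 2,
# KO/WT BEC slope ratio = 2, equal isolated-lick rates, lower KO bout rate
# and bout size, and the KO late-session (120-150 min) rate elevation.
_WT = PhenotypeParams(
    bout_rate=PiecewiseRate(SEGMENT_EDGES, (16.0, 5.0, 5.0, 5.0)),
    bout_size_mean=28.0,
    within_ili=GammaSpec(mean=0.15, shape=4.0),  # ~7 Hz licking
    bout_lick_duration=LognormalSpec(median=0.050, sigma=0.30),
    isolated_lick_rate=30.0,
    nonbout_lick_duration=LognormalSpec(median=0.075, sigma=0.40),
    volume_per_lick=(1.2, 0.25),
    bec_slope=25.0,
    bec_noise_sd=8.0,
    intake_noise_sd=0.10,
)
_KO = replace(
    _WT,
    bout_rate=PiecewiseRate(SEGMENT_EDGES, (10.0, 3.5, 8.0, 3.5)),
    bout_size_mean=18.0,
    nonbout_lick_duration=LognormalSpec(median=0.150, sigma=0.40),
    bec_slope=50.0,
)

PRESETS = {
    "wild_type": _WT,
    "adh1_ko": _KO,
    # Saccharin drinking shows no genotype differences: both groups use the
    # control parameters (BEC fields are inert for non-ethanol fluids).
    "saccharin": _WT,
}


def make_phenotype(preset: str) -> PhenotypeParams:
    """Return the documented default parameters for a named preset."""
    try:
        return PRESETS[preset]
    except KeyError:
        raise ValidationError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        ) from None


@dataclass(frozen=True)
class CohortSpec:
    """A balanced multi-group cohort of single-session animals."""

    n_per_group: int
    groups: tuple[tuple[str, PhenotypeParams], ...]
    session_length: float = 7200.0
    seed: int = 0
    body_mass: tuple[float, float] = (25.0, 2.0)  # grams (mean, sd)
    fluid: str = "ethanol20"
    day_index: int = 1
    with_bec: bool = True
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be >= 1")


@dataclass
class SessionTruth:
    """Ground truth for one simulated session (for test harnesses)."""

    bout_sizes: list[int]
    bout_onsets: list[float]  # onset of each bout's first lick
    n_isolated: int
    detectable_bouts: int  # generated bouts with >= init_n licks


@dataclass
class Cohort:
    manifests: list[SessionRecord]
    licks: dict[str, list[Lick]]
    truths: dict[str, SessionTruth]


def _truncated_gamma(
    spec: GammaSpec, cap: float, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Gamma samples rejected above ``cap`` (cap far in the tail by default)."""
    out = spec.sample(rng, size)
    for _ in range(100):
        bad = out > cap
        if not bad.any():
            return out
        out[bad] = spec.sample(rng, int(bad.sum()))
    raise ValidationError(
        f"could not draw gamma(mean={spec.mean}) below cap {cap}; "
        "lower the mean or raise init_ili_max"
    )


def simulate_session(
    params: PhenotypeParams,
    session_length: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    segmentation: SegmentationParams = SegmentationParams(),
    session_id: str = "",
    channel: int = 0,
) -> list[Lick]:
    """Simulate one session's lick train. See the module docstring."""
    licks, _ = simulate_session_with_truth(
        params, session_length, seed=seed, rng=rng,
        segmentation=segmentation, session_id=session_id, channel=channel,
    )
    return licks


def simulate_session_with_truth(
    params: PhenotypeParams,
    session_length: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    segmentation: SegmentationParams = SegmentationParams(),
    session_id: str = "",
    channel: int = 0,
) -> tuple[list[Lick], SessionTruth]:
    """Simulate a session and return the generated ground truth alongside."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if session_length <= 0:
        raise ValidationError("session_length must be > 0")
    gap = segmentation.term_gap + _SPACING_MARGIN

    # --- bout anchors: piecewise-constant Poisson process -------------------
    anchors: list[float] = []
    for lo, hi, rate in params.bout_rate.segments_within(session_length):
        n = rng.poisson(rate / 3600.0 * (hi - lo))
        anchors.extend(np.sort(rng.uniform(lo, hi, n)).tolist())
    anchors.sort()

    onsets: list[float] = []
    durations: list[float] = []
    bout_sizes: list[int] = []
    bout_onsets: list[float] = []
    prev_last = -math.inf
    for anchor in anchors:
        if anchor <= prev_last + gap:
            continue  # too close to the previous bout: drop, keeping spacing
        size = int(rng.geometric(1.0 / params.bout_size_mean))
        ilis = _truncated_gamma(
            params.within_ili, segmentation.init_ili_max, rng, size - 1
        )
        bout_t = anchor + np.concatenate([[0.0], np.cumsum(ilis)])
        bout_t = bout_t[bout_t < session_length]
        if bout_t.size == 0:
            continue
        durs = params.bout_lick_duration.sample(rng, bout_t.size)
        # contact must end before the next lick begins (and the session end)
        gaps = np.diff(np.append(bout_t, session_length))
        durs = np.minimum(durs, np.maximum(gaps * 0.9, 1e-4))
        onsets.extend(bout_t.tolist())
        durations.extend(durs.tolist())
        bout_sizes.append(int(bout_t.size))
        bout_onsets.append(float(bout_t[0]))
        prev_last = float(bout_t[-1])

    # --- isolated licks: homogeneous Poisson with spacing rejection ---------
    n_iso_target = rng.poisson(params.isolated_lick_rate / 3600.0 * session_length)
    existing = np.array(onsets, dtype=float)
    iso_times: list[float] = []
    budget = 100 * max(n_iso_target, 1)
    placed = 0
    while placed < n_iso_target:
        if budget <= 0:
            raise ValidationError(
                "isolated-lick rejection sampling exceeded its retry budget; "
                "lower the bout or isolated-lick rates"
            )
        budget -= 1
        t = float(rng.uniform(0.0, session_length))
        pool = np.concatenate([existing, np.array(iso_times)]) if iso_times else existing
        if pool.size and np.min(np.abs(pool - t)) <= gap:
            continue
        iso_times.append(t)
        placed += 1
    iso_durs = params.nonbout_lick_duration.sample(rng, len(iso_times))
    # keep isolated contacts comfortably shorter than the spacing margin
    iso_durs = np.minimum(iso_durs, 2.0)
    onsets.extend(iso_times)
    durations.extend(iso_durs.tolist())

    order = np.argsort(onsets)
    licks = [
        Lick(float(onsets[i]), float(durations[i]), channel, session_id)
        for i in order
    ]
    truth = SessionTruth(
        bout_sizes=bout_sizes,
        bout_onsets=bout_onsets,
        n_isolated=len(iso_times),
        detectable_bouts=sum(1 for s in bout_sizes if s >= segmentation.init_n),
    )
    return licks, truth


def simulate_raw_signal(
    licks: Sequence[Lick],
    sample_period: float,
    baseline: int = 120,
    amplitude: int = 30,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    t_end: float | None = None,
    delta: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a raw capacitance trace from a lick train.

    The trace sits at ``baseline`` and steps up by ``amplitude`` for each
    lick's contact window ``[onset, onset + duration)``.  Jitter is drawn as
    bounded uniform integers (bound = round(sqrt(3) * jitter_sd), matching
    the requested standard deviation) so that consecutive-sample differences
    can never reach the detection threshold on their own; the call rejects
    parameter combinations where jitter could mask or fake a transition.
    Licks shorter than one sample period would fall between samples and are
    rejected.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if sample_period <= 0:
        raise ValidationError("sample_period must be > 0")
    lst = sorted(licks, key=lambda l: l.onset)
    for a, b in zip(lst, lst[1:]):
        if a.end > b.onset:
            raise ValidationError(
                f"overlapping licks at {a.onset:.3f} and {b.onset:.3f}"
            )
    for lk in lst:
        if lk.duration < sample_period:
            raise ValidationError(
                f"lick at {lk.onset:.3f} shorter than one sample period"
            )
    bound = int(round(math.sqrt(3.0) * jitter_sd))
    if 2 * bound >= delta:
        raise ValidationError(
            f"jitter bound {bound} too large for detection delta {delta}"
        )
    if amplitude - 2 * bound < delta:
        raise ValidationError(
            f"amplitude {amplitude} minus jitter span must stay >= delta {delta}"
        )
    if t_end is None:
        t_end = (lst[-1].end if lst else 0.0) + 10 * sample_period
    n = int(math.floor(t_end / sample_period)) + 1
    t = np.arange(n) * sample_period
    v = np.full(n, baseline, dtype=np.int64)
    for lk in lst:
        i0 = int(np.searchsorted(t, lk.onset, side="left"))
        i1 = int(np.searchsorted(t, lk.end, side="left"))
        v[i0:i1] += amplitude
    if bound > 0:
        v = v + rng.integers(-bound, bound + 1, size=n)
    return t, v


def simulate_cohort(spec: CohortSpec, fluid_spec: FluidSpec | None = None) -> Cohort:
    """Simulate a balanced cohort: one session per animal per group.

    Per animal, intake is the summed per-lick volume (with per-lick volume
    noise plus a session-level intake noise term), written back as bottle
    masses so that the intake conversion inverts exactly; blood ethanol is
    ``bec_slope * intake + noise``.  Identical specs (including the seed)
    produce identical cohorts.
    """
    if fluid_spec is None:
        from .intake_pk import FLUID_SPECS

        fluid_spec = FLUID_SPECS[spec.fluid]
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(len(spec.groups) * spec.n_per_group)
    manifests: list[SessionRecord] = []
    licks: dict[str, list[Lick]] = {}
    truths: dict[str, SessionTruth] = {}
    k = 0
    for label, params in spec.groups:
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(streams[k])
            k += 1
            animal_id = f"{label}_{i:02d}"
            session_id = f"{animal_id}_d{spec.day_index}"
            body = float(
                np.clip(
                    rng.normal(spec.body_mass[0], spec.body_mass[1]), 15.0, 45.0
                )
            )
            session_licks, truth = simulate_session_with_truth(
                params,
                spec.session_length,
                rng=rng,
                segmentation=spec.segmentation,
                session_id=session_id,
            )
            n_licks = len(session_licks)
            vol_mean, vol_sd = params.volume_per_lick
            if vol_sd > 0 and n_licks:
                vols = np.clip(
                    rng.normal(vol_mean, vol_sd, n_licks), 0.0, None
                )
                volume_ul = float(vols.sum())
            else:
                volume_ul = vol_mean * n_licks
            mass_diff = volume_ul / 1000.0 * fluid_spec.solution_density
            if params.intake_noise_sd > 0:
                # express the g/kg noise as an equivalent solution mass
                if fluid_spec.ethanol_vol_fraction > 0:
                    per_gkg = (
                        (body / 1000.0)
                        / (fluid_spec.ethanol_vol_fraction * fluid_spec.ethanol_density)
                        * fluid_spec.solution_density
                    )
                    mass_diff += rng.normal(0.0, params.intake_noise_sd) * per_gkg
            mass_diff = max(mass_diff, 0.0)
            record = SessionRecord(
                session_id=session_id,
                animal_id=animal_id,
                genotype=label if label in ("wild_type", "adh1_ko") else "wild_type",
                sex="F" if i % 2 == 0 else "M",
                fluid=spec.fluid,
                session_length=spec.session_length,
                bottle_mass_pre=45.0,
                bottle_mass_post=45.0 - mass_diff,
                body_mass=body,
                day_index=spec.day_index,
            )
            if spec.with_bec and fluid_spec.ethanol_vol_fraction > 0:
                intake = compute_intake(record, fluid_spec)
                bec = params.bec_slope * intake
                if params.bec_noise_sd > 0:
                    bec += rng.normal(0.0, params.bec_noise_sd)
                record.bec = float(bec)
            manifests.append(record)
            licks[session_id] = session_licks
            truths[session_id] = truth
    return Cohort(manifests=manifests, licks=licks, truths=truths)


def default_cohort_spec(
    n_per_group: int = 12,
    session_length: float = 7200.0,
    seed: int = 0,
    fluid: str = "ethanol20",
) -> CohortSpec:
    """Two-group (control vs ADH1-null) cohort with the default presets.

    For saccharin cohorts both groups share the genotype-independent
    saccharin parameters while keeping their genotype labels.
    """
    if fluid == "saccharin01":
        params = make_phenotype("saccharin")
        groups = (("wild_type", params), ("adh1_ko", params))
    else:
        groups = (
            ("wild_type", make_phenotype("wild_type")),
            ("adh1_ko", make_phenotype("adh1_ko")),
        )
    return CohortSpec(
        n_per_group=n_per_group,
        groups=groups,
        session_length=session_length,
        seed=seed,
        fluid=fluid,
    )
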
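"""Headless engines for the three rehabilitation games.

* **Daring Escape** (VOR): the head's yaw (or pitch) angle steers a character
  past obstacles that appear at the prescribed pace — one per half-cycle,
  alternating sides.  An obstacle is avoided when the head crosses the avoid
  threshold toward the cued side before the half-cycle deadline; each avoided
  obstacle earns a coin.  The obstacle pace derives from the prescription:
  either the prescribed frequency directly, or from the desired angular
  velocity via the constant-speed sweep model ``f = v / (4 A)`` (one full
  cycle covers four amplitudes of travel).

* **Treasure Hunter** (weight shift): the pelvic lean positions the character
  on screen (``gain`` screen-units per degree); coins spawn one at a time in
  the cued direction and are banked by dwelling on the coin and then
  returning to the treasure chest at the origin.

* **Balancing Act** (single-leg stance): every scoring interval awards two,
  one, or zero coins depending on the resultant pelvic tilt (level pelvis =
  two coins).

All engines are deterministic given the series and the configuration (the
only randomness, the omnidirectional coin order, is seeded), and emit a
:class:`GameResult` with coins, opportunities, the fraction of the maximum
attainable score, and a trophy tier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kinematics import resultant_angle
from .prescriptions import ExercisePrescription
from .series import AngleSeries

TROPHY_CUTOFFS = (("gold", 0.90), ("silver", 0.75), ("bronze", 0.50))

_COMPASS = np.array(
    [
        (0.0, 1.0), (np.sqrt(0.5), np.sqrt(0.5)), (1.0, 0.0),
        (np.sqrt(0.5), -np.sqrt(0.5)), (0.0, -1.0),
        (-np.sqrt(0.5), -np.sqrt(0.5)), (-1.0, 0.0),
        (-np.sqrt(0.5), np.sqrt(0.5)),
    ]
)  # (ML, AP) unit vectors: N, NE, E, SE, S, SW, W, NW


@dataclass
class GameConfig:
    """Game mechanics parameters; unset geometry derives from the prescription.

    Defaults (artifact conventions, configurable): avoid threshold = half the
    prescribed amplitude; coin placed at 80 % of the on-screen prescribed
    excursion with a collection radius of 25 % of it; 0.5 s dwell to pick a
    coin up; tilt bands 2 deg / 5 deg for the 2/1/0-coin rule at 1 s scoring
    intervals; trophies at 90/75/50 % of the maximum score.
    """

    prescription: ExercisePrescription
    gain_units_per_deg: float = 10.0
    avoid_threshold_deg: Optional[float] = None
    coin_radius: Optional[float] = None
    coin_reach_frac: float = 0.8
    dwell_s: float = 0.5
    tilt_bands_deg: tuple = (2.0, 5.0)
    interval_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.avoid_threshold_deg is None:
            self.avoid_threshold_deg = 0.5 * self.prescription.amplitude_deg
        if self.coin_radius is None:
            self.coin_radius = (
                0.25 * self.gain_units_per_deg * self.prescription.amplitude_deg
            )
        low, high = self.tilt_bands_deg
        if not (0 < low < high):
            raise ValueError("tilt_bands_deg must satisfy 0 < low < high")
        for name in ("gain_units_per_deg", "dwell_s", "interval_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ObstacleSchedule:
    """When obstacles appear, which side is cued, and the underlying pace."""

    spawn_times: np.ndarray
    cued_signs: np.ndarray       # +1 / -1 toward the positive / negative axis
    cued_sides: tuple            # human-readable side labels
    rate_per_s: float            # head rotations (full cycles) per second

    @property
    def half_period_s(self) -> float:
        return 1.0 / (2.0 * self.rate_per_s)

    @property
    def n_obstacles(self) -> int:
        return int(self.spawn_times.shape[0])


@dataclass(frozen=True)
class GameResult:
    """Outcome of one headless game run."""

    game: str
    coins: int
    opportunities: int
    max_coins: int
    fraction: float
    trophy: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GameResult":
        return cls(
            game=str(d["game"]),
            coins=int(d["coins"]),
            opportunities=int(d["opportunities"]),
            max_coins=int(d["max_coins"]),
            fraction=float(d["fraction"]),
            trophy=str(d["trophy"]),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def obstacle_rate(prescription: ExercisePrescription) -> tuple[float, ObstacleSchedule]:
    """Head rotations per second and the obstacle schedule they imply.

    ``f = v / (4 A)`` under the constant-speed sweep model when the angular
    velocity is given; the prescribed frequency when given directly.  When
    both are given they must agree to 1 %.  One obstacle spawns per
    half-cycle (2 f per second), alternating cued sides, over the trial.
    """
    A = prescription.amplitude_deg
    f_direct = prescription.frequency_hz if prescription.frequency_hz > 0 else None
    v = prescription.angular_velocity_deg_s
    if A <= 0:
        raise ValueError("amplitude_deg must be positive")
    if f_direct is None and v is None:
        raise ValueError("need frequency_hz or angular_velocity_deg_s")
    f_from_v = v / (4.0 * A) if v is not None else None
    if f_direct is not None and f_from_v is not None:
        if abs(f_from_v - f_direct) > 0.01 * f_direct:
            raise ValueError(
                f"frequency {f_direct:g} Hz and angular velocity {v:g} deg/s "
                f"disagree (velocity implies {f_from_v:g} rotations/s)"
            )
    rate = f_direct if f_direct is not None else f_from_v

    n = int(np.floor(prescription.duration_s * 2.0 * rate + 1e-9))
    spawn_times = np.arange(n) / (2.0 * rate)
    cued_signs = np.where(np.arange(n) % 2 == 0, 1, -1)
    if prescription.exercise == "vor_pitch":
        labels = {1: "up", -1: "down"}
    else:
        labels = {1: "left", -1: "right"}
    cued_sides = tuple(labels[int(s)] for s in cued_signs)
    return rate, ObstacleSchedule(
        spawn_times=spawn_times,
        cued_signs=cued_signs,
        cued_sides=cued_sides,
        rate_per_s=rate,
    )


def play_daring_escape(series: AngleSeries, config: GameConfig) -> GameResult:
    """Score a VOR trial against the obstacle schedule.

    An obstacle is avoided iff the primary-channel angle crosses the avoid
    threshold on the cued side within the obstacle's half-cycle deadline.
    """
    prescription = config.prescription
    if not prescription.is_vor:
        raise ValueError(
            f"Daring Escape requires a VOR exercise, got {prescription.exercise}"
        )
    if series.reference != "neutral-relative":
        raise ValueError("Daring Escape requires a neutral-relative series")
    rate, schedule = obstacle_rate(prescription)
    t = series.t - series.t[0]
    duration = series.n_samples / series.sample_rate_hz
    last_deadline = schedule.spawn_times[-1] + schedule.half_period_s
    if duration + 1.0 / series.sample_rate_hz < last_deadline:
        raise ValueError(
            f"series ({duration:.3g} s) shorter than the obstacle schedule "
            f"({last_deadline:.3g} s)"
        )
    x = series.channel(prescription.primary_channel)
    coins = 0
    for spawn, sign in zip(schedule.spawn_times, schedule.cued_signs):
        mask = (t >= spawn) & (t < spawn + schedule.half_period_s)
        if mask.any() and np.max(sign * x[mask]) >= config.avoid_threshold_deg:
            coins += 1
    n = schedule.n_obstacles
    return _result("daring_escape", coins, opportunities=n, max_coins=n)


def _first_run_end(ok: np.ndarray, start: int, run_len: int) -> Optional[int]:
    """Index just past the first run of *run_len* consecutive True from *start*."""
    sub = ok[start:]
    if run_len <= 1:
        hits = np.flatnonzero(sub)
        return start + hits[0] + 1 if hits.size else None
    kernel = np.convolve(sub.astype(int), np.ones(run_len, dtype=int), mode="valid")
    hits = np.flatnonzero(kernel == run_len)
    return start + hits[0] + run_len if hits.size else None


def play_treasure_hunter(series: AngleSeries, config: GameConfig) -> GameResult:
    """Score a weight-shift trial: dwell on each spawned coin, bank it at the chest.

    Coins spawn sequentially (laterally for ws_ml, sagittally for ws_ap, at
    eight compass points in seeded order for ws_omni) at 80 % of the
    prescribed on-screen excursion; one is banked after the character dwells
    within the coin radius for ``dwell_s`` and then returns within the same
    radius of the origin.  Opportunities = prescribed cycles in the trial.
    """
    prescription = config.prescription
    if not prescription.is_weight_shift:
        raise ValueError(
            f"Treasure Hunter requires a weight-shift exercise, got "
            f"{prescription.exercise}"
        )
    if series.reference != "neutral-relative":
        raise ValueError("Treasure Hunter requires a neutral-relative series")
    g = config.gain_units_per_deg
    pos = np.column_stack([g * series.ml, g * series.ap])
    fs = series.sample_rate_hz
    dwell_n = max(1, int(round(config.dwell_s * fs)))
    n_opp = max(1, int(np.floor(prescription.duration_s * prescription.frequency_hz + 1e-9)))
    reach = config.coin_reach_frac * g * prescription.amplitude_deg

    if prescription.exercise == "ws_ml":
        dirs = [(1.0, 0.0), (-1.0, 0.0)]
        targets = [np.array(dirs[k % 2]) * reach for k in range(n_opp)]
    elif prescription.exercise == "ws_ap":
        dirs = [(0.0, 1.0), (0.0, -1.0)]
        targets = [np.array(dirs[k % 2]) * reach for k in range(n_opp)]
    else:  # ws_omni: compass points, seeded order per block of eight
        rng = np.random.default_rng(config.seed)
        order: list[int] = []
        while len(order) < n_opp:
            order.extend(rng.permutation(8).tolist())
        targets = [_COMPASS[order[k]] * reach for k in range(n_opp)]

    origin_dist = np.linalg.norm(pos, axis=1)
    coins = 0
    i = 0
    for target in targets:
        near_coin = np.linalg.norm(pos - target, axis=1) <= config.coin_radius
        j = _first_run_end(near_coin, i, dwell_n)
        if j is None:
            break
        home = np.flatnonzero(origin_dist[j:] <= config.coin_radius)
        if home.size == 0:
            break
        i = j + int(home[0]) + 1
        coins += 1
    return _result("treasure_hunter", coins, opportunities=n_opp, max_coins=n_opp)


def play_balancing_act(series: AngleSeries, config: GameConfig) -> GameResult:
    """Score a single-leg stance trial: 2/1/0 coins per interval by pelvic tilt.

    Per scoring interval the mean resultant tilt theta earns 2 coins below the
    low band, 1 between the bands, 0 at or above the high band.
    """
    prescription = config.prescription
    if not prescription.is_single_leg:
        raise ValueError(
            f"Balancing Act requires a single-leg exercise, got "
            f"{prescription.exercise}"
        )
    if series.reference != "neutral-relative":
        raise ValueError("Balancing Act requires a neutral-relative series")
    fs = series.sample_rate_hz
    duration = series.n_samples / fs
    samples_per_interval = int(round(config.interval_s * fs))
    n_intervals = series.n_samples // samples_per_interval
    if n_intervals < 1:
        raise ValueError("series shorter than one scoring interval")
    tilt = resultant_angle(series.ml, series.ap)
    low, high = config.tilt_bands_deg
    coins = 0
    for k in range(n_intervals):
        theta = float(np.mean(tilt[k * samples_per_interval:(k + 1) * samples_per_interval]))
        if theta < low:
            coins += 2
        elif theta < high:
            coins += 1
    return _result(
        "balancing_act", coins, opportunities=n_intervals, max_coins=2 * n_intervals
    )


def award_trophy(fraction: float) -> str:
    """Trophy tier for a score fraction; boundary values take the higher tier."""
    for tier, cutoff in TROPHY_CUTOFFS:
        if fraction >= cutoff:
            return tier
    return "none"


def _result(game: str, coins: int, opportunities: int, max_coins: int) -> GameResult:
    fraction = coins / max_coins if max_coins else 0.0
    return GameResult(
        game=game,
        coins=coins,
        opportunities=opportunities,
        max_coins=max_coins,
        fraction=fraction,
        trophy=award_trophy(fraction),
    )


GAME_FOR_EXERCISE = {
    "vor_yaw": "daring_escape",
    "vor_pitch": "daring_escape",
    "ws_ml": "treasure_hunter",
    "ws_ap": "treasure_hunter",
    "ws_omni": "treasure_hunter",
    "sls_left": "balancing_act",
    "sls_right": "balancing_act",
}

PLAYERS = {
    "daring_escape": play_daring_escape,
    "treasure_hunter": play_treasure_hunter,
    "balancing_act": play_balancing_act,
}


def play(game: str, series: AngleSeries, config: GameConfig) -> GameResult:
    """Dispatch to a game engine, checking game/exercise compatibility."""
    if game not in PLAYERS:
        raise ValueError(f"unknown game {game!r}")
    expected = GAME_FOR_EXERCISE[config.prescription.exercise]
    if game != expected:
        raise ValueError(
            f"game {game!r} does not match exercise "
            f"{config.prescription.exercise!r} (expected {expected!r})"
        )
    return PLAYERS[game](series, config)
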
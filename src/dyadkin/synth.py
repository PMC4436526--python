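"""Synthetic actor/imitator dyads with known ground truth.

Emulates the pegboard imitation game: a 4x4 grid of vertical rods (60 mm
spacing, heights 30/70/110/150 mm front-to-back) carrying three 40 mm
balls.  Each 20 s trial the actor transports a ball along 10 adjacent-peg
moves (simple: one ball; complex: all three balls) and returns the hand to
a start marker, with 5 s rests between the 10 trials of a session.  The
imitator is modelled as a lagged, gain-perturbed copy of the actor plus
low-passed Gaussian noise, which is the coupling structure the analysis
pipeline is designed to recover.

Hand paths are minimum-jerk point-to-point segments with a via-point above
the pegs; the arm (wrist -> elbow -> shoulder) follows a two-link inverse
kinematic model so that derived joint angles are smooth and in range.
Orientation channels are low-amplitude signals driven by hand speed — they
exist so all 42 channels are analyzable, not to be biomechanically
faithful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .core import (
    CHANNELS,
    DEFAULT_SAMPLE_RATE,
    ORIENTATION_DOFS,
    TRACKERS,
    Difficulty,
    Feedback,
    Recording,
    Role,
    TrialWindow,
)

log = logging.getLogger(__name__)

BALL_IDS = ("red", "blue", "yellow")


@dataclass(frozen=True)
class BoardGeometry:
    """Pegboard geometry in the recording frame (mm).

    Rows run front (nearest the player, small y) to back; columns left to
    right along x.  ``peg_heights`` increase front-to-back.  The start
    marker sits at the near-right corner, comfortably outside the
    trial-detection radius of every peg.
    """

    spacing_mm: float = 60.0
    peg_heights_mm: tuple[float, ...] = (30.0, 70.0, 110.0, 150.0)
    ball_diameter_mm: float = 40.0
    grid_origin: tuple[float, float] = (30.0, 150.0)
    start_point: tuple[float, float, float] = (280.0, 20.0, 25.0)

    def __post_init__(self) -> None:
        if len(self.peg_heights_mm) != 4:
            raise ValueError("expected 4 peg rows")
        if any(b >= a for a, b in zip(self.peg_heights_mm[1:], self.peg_heights_mm)):
            raise ValueError("peg heights must increase front-to-back")
        if self.spacing_mm != 60.0:
            raise ValueError("inter-rod spacing is fixed at 60 mm")

    @property
    def n_pegs(self) -> int:
        return 16

    def peg_xy(self, peg: tuple[int, int]) -> np.ndarray:
        row, col = peg
        if not (0 <= row < 4 and 0 <= col < 4):
            raise ValueError(f"peg {peg} outside the 4x4 grid")
        x0, y0 = self.grid_origin
        return np.array([x0 + col * self.spacing_mm, y0 + row * self.spacing_mm])

    def peg_top_z(self, peg: tuple[int, int]) -> float:
        return self.peg_heights_mm[peg[0]]

    def ball_center(self, peg: tuple[int, int]) -> np.ndarray:
        """Grasp point: center of a ball resting on a peg."""
        xy = self.peg_xy(peg)
        z = self.peg_top_z(peg) + self.ball_diameter_mm / 2
        return np.array([xy[0], xy[1], z])


@dataclass(frozen=True)
class Move:
    ball_id: str
    from_peg: tuple[int, int]
    to_peg: tuple[int, int]


@dataclass
class MoveSequence:
    moves: list[Move]
    difficulty: Difficulty

    def validate(self) -> "MoveSequence":
        if len(self.moves) != 10:
            raise ValueError("a trial consists of exactly 10 moves")
        for m in self.moves:
            dr = abs(m.from_peg[0] - m.to_peg[0])
            dc = abs(m.from_peg[1] - m.to_peg[1])
            if dr + dc != 1:
                raise ValueError(f"move {m} is not between adjacent pegs")
        balls = {m.ball_id for m in self.moves}
        if self.difficulty == Difficulty.simple and len(balls) != 1:
            raise ValueError("simple trials use a single ball")
        if self.difficulty == Difficulty.complex and len(balls) != 3:
            raise ValueError("complex trials must use all three balls")
        return self


@dataclass
class GroundTruth:
    """Generator-side ledger of everything the pipeline should recover."""

    true_lag_s: float = 0.0
    coupling_noise_sd: float = 0.0
    gain: float = 1.0
    spike_indices: dict[str, np.ndarray] = field(default_factory=dict)
    trial_windows: list[TrialWindow] = field(default_factory=list)
    trial_spans: list[TrialWindow] = field(default_factory=list)
    move_sequences: list[MoveSequence] = field(default_factory=list)


def _neighbors(peg: tuple[int, int]) -> list[tuple[int, int]]:
    r, c = peg
    cand = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
    return [(rr, cc) for rr, cc in cand if 0 <= rr < 4 and 0 <= cc < 4]


def random_placement(rng: np.random.Generator) -> dict[str, tuple[int, int]]:
    """Place the three balls on distinct random pegs."""
    pegs = [(int(i) // 4, int(i) % 4) for i in rng.choice(16, size=3, replace=False)]
    return dict(zip(BALL_IDS, pegs))


def sample_move_sequence(
    difficulty: Difficulty | str,
    board_state: dict[str, tuple[int, int]],
    rng: np.random.Generator,
    max_restarts: int = 20,
) -> MoveSequence:
    """Draw 10 legal adjacent-peg moves, updating ``board_state`` in place.

    Simple difficulty walks a single ball; complex partitions the 10 moves
    over all three balls (each at least once), moving each ball in a
    consecutive block.  A destination peg must be unoccupied.  If the walk
    dead-ends, the board is re-seeded from a fresh random placement.
    """
    difficulty = Difficulty(difficulty)
    if len(set(board_state.values())) != len(board_state) or len(board_state) != 3:
        raise ValueError("board_state must place 3 balls on distinct pegs")

    for attempt in range(max_restarts):
        state = dict(board_state)
        if difficulty == Difficulty.simple:
            plan = [(str(rng.choice(BALL_IDS)), 10)]
        else:
            cuts = np.sort(rng.choice(np.arange(1, 10), size=2, replace=False))
            counts = [int(cuts[0]), int(cuts[1] - cuts[0]), int(10 - cuts[1])]
            order = list(rng.permutation(list(BALL_IDS)))
            plan = list(zip(order, counts))
        moves: list[Move] = []
        ok = True
        for ball, count in plan:
            for _ in range(count):
                occupied = set(state.values())
                options = [p for p in _neighbors(state[ball]) if p not in occupied]
                if not options:
                    ok = False
                    break
                to = options[int(rng.integers(len(options)))]
                moves.append(Move(ball, state[ball], to))
                state[ball] = to
            if not ok:
                break
        if ok:
            board_state.clear()
            board_state.update(state)
            return MoveSequence(moves, difficulty).validate()
        log.info("move walk dead-ended (attempt %d); re-seeding placement", attempt)
        board_state.clear()
        board_state.update(random_placement(rng))
    raise RuntimeError("could not sample a legal move sequence")


def min_jerk_segment(
    p0: np.ndarray, p1: np.ndarray, duration_s: float, fs: float
) -> np.ndarray:
    """Minimum-jerk point-to-point trajectory, endpoints included.

    Position follows the quintic profile s(tau) = 10 tau^3 - 15 tau^4
    + 6 tau^5, which has zero velocity and acceleration at both ends.
    Returns an (n, k) array for k-dimensional endpoints.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    p0 = np.atleast_1d(np.asarray(p0, dtype=float))
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    n = max(2, int(round(duration_s * fs)))
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return p0[None, :] + s[:, None] * (p1 - p0)[None, :]


def _quintic(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _smooth_noise(
    n: int, fs: float, cutoff_hz: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Low-passed Gaussian noise rescaled to the requested SD."""
    if sd == 0 or n < 20:
        return np.zeros(n)
    white = rng.standard_normal(n)
    b, a = signal.butter(2, cutoff_hz, fs=fs)
    smooth = signal.filtfilt(b, a, white)
    s = smooth.std()
    return smooth / s * sd if s > 0 else np.zeros(n)


class _PathBuilder:
    """Accumulates (target, duration, aperture) waypoints into sample arrays."""

    def __init__(self, start: np.ndarray, start_aperture: float, fs: float):
        self.fs = fs
        self.pos = start.astype(float).copy()
        self.ap = float(start_aperture)
        self.chunks_pos: list[np.ndarray] = []
        self.chunks_ap: list[np.ndarray] = []
        self._t = 0.0  # continuous time, for drift-free sample counts

    def hold(self, duration_s: float) -> None:
        n = self._n_samples(duration_s)
        self.chunks_pos.append(np.tile(self.pos, (n, 1)))
        self.chunks_ap.append(np.full(n, self.ap))

    def segment(self, target: np.ndarray, duration_s: float, aperture: float) -> None:
        n = self._n_samples(duration_s)
        tau = np.arange(1, n + 1) / n
        s = _quintic(tau)
        self.chunks_pos.append(self.pos[None, :] + s[:, None] * (target - self.pos))
        self.chunks_ap.append(self.ap + s * (aperture - self.ap))
        self.pos = np.asarray(target, dtype=float).copy()
        self.ap = float(aperture)

    def _n_samples(self, duration_s: float) -> int:
        start = int(round(self._t * self.fs))
        self._t += duration_s
        return int(round(self._t * self.fs)) - start

    def build(self) -> tuple[np.ndarray, np.ndarray]:
        return np.concatenate(self.chunks_pos), np.concatenate(self.chunks_ap)


# Plausible adult arm geometry (mm); only needs to yield smooth, in-range
# joint angles, not anthropometric fidelity.
_UPPER_ARM_MM = 300.0
_FOREARM_MM = 260.0
_SHOULDER_BASE = np.array([240.0, -150.0, 400.0])
_HEAD_BASE = np.array([240.0, -250.0, 600.0])
_WRIST_OFFSET = np.array([0.0, -70.0, 25.0])
_LITTLE_OFFSET = np.array([25.0, -15.0, 5.0])

_APERTURE_HOLD = 42.0   # around a 40 mm ball
_APERTURE_OPEN = 60.0
_APERTURE_START = 30.0  # gripping the start marker


def _two_link_elbow(S: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Elbow-down two-link inverse kinematics, vectorized over samples.

    The elbow lies in the vertical plane through shoulder and wrist, below
    the shoulder-wrist line.  Link lengths are scaled up (with a warning)
    if a wrist sample is out of reach.
    """
    L1, L2 = _UPPER_ARM_MM, _FOREARM_MM
    d_vec = W - S
    d = np.linalg.norm(d_vec, axis=1)
    reach = np.max(d)
    if reach > (L1 + L2) - 5.0:
        scale = reach / ((L1 + L2) - 5.0)
        L1, L2 = L1 * scale, L2 * scale
        log.warning("wrist out of reach; scaling arm segments by %.3f", scale)
    a = d_vec / d[:, None]
    t = (L1**2 - L2**2 + d**2) / (2 * d)
    h = np.sqrt(np.maximum(L1**2 - t**2, 0.0))
    z_hat = np.array([0.0, 0.0, 1.0])
    v = z_hat[None, :] - (a @ z_hat)[:, None] * a
    v_norm = np.linalg.norm(v, axis=1)
    # Degenerate (vertical) shoulder-wrist line: fall back to -y.
    fallback = np.array([0.0, -1.0, 0.0])
    v = np.where(v_norm[:, None] > 1e-9, v / np.maximum(v_norm, 1e-12)[:, None],
                 fallback[None, :])
    return S + t[:, None] * a - h[:, None] * v


def _orientation_channels(
    positions: dict[str, np.ndarray], fs: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Low-amplitude orientation signals coupled to each tracker's speed."""
    out: dict[str, np.ndarray] = {}
    for ti, tracker in enumerate(TRACKERS):
        pos = positions[tracker]
        n = len(pos)
        vel = np.gradient(pos, axis=0) * fs
        speed = np.linalg.norm(vel, axis=1)
        b, a = signal.butter(2, 4.0, fs=fs)
        speed = signal.filtfilt(b, a, speed)
        s = speed.std()
        drive = (speed - speed.mean()) / s if s > 0 else np.zeros(n)
        for di, dof in enumerate(ORIENTATION_DOFS):
            base = 20.0 * ti - 15.0 * di + float(rng.uniform(-10, 10))
            amp = float(rng.uniform(5.0, 12.0))
            out[f"{tracker}_{dof}"] = (
                base + amp * drive + _smooth_noise(n, fs, 2.0, 1.0, rng)
            )
    return out


def synth_actor(
    board: BoardGeometry,
    difficulty: Difficulty | str,
    rng: np.random.Generator,
    *,
    n_trials: int = 10,
    trial_s: float = 20.0,
    rest_s: float = 5.0,
    fs: float = DEFAULT_SAMPLE_RATE,
    feedback: Feedback | str = Feedback.face_to_face,
    person_id: str = "actor",
    jitter_mm: float = 0.3,
) -> tuple[Recording, GroundTruth]:
    """Simulate one actor session: ``n_trials`` trials with rests between.

    Session length is exactly ``(n_trials*trial_s + (n_trials-1)*rest_s) *
    fs`` samples.  Within each trial the usable time is split uniformly
    over one reach, ten moves, and one return; ball transports arc over a
    via-point 30 mm above the taller of the two pegs.  The ground truth
    records the cue-aligned trial spans, the motion-defined windows the
    segmenter should find, and every move sequence.
    """
    difficulty = Difficulty(difficulty)
    start = np.asarray(board.start_point, dtype=float)
    placement = random_placement(rng)
    gt = GroundTruth()

    builder = _PathBuilder(start, _APERTURE_START, fs)
    n_trial = int(round(trial_s * fs))
    n_rest = int(round(rest_s * fs))
    seg_unit = trial_s / 12.0  # reach + 10 moves + return

    for trial in range(n_trials):
        t0 = sum(len(c) for c in builder.chunks_ap)
        seq = sample_move_sequence(difficulty, placement, rng)
        gt.move_sequences.append(seq)
        held: str | None = None
        for i, move in enumerate(seq.moves):
            grasp_from = board.ball_center(move.from_peg)
            grasp_to = board.ball_center(move.to_peg)
            via = (grasp_from + grasp_to) / 2
            via[2] = max(board.peg_top_z(move.from_peg),
                         board.peg_top_z(move.to_peg)) + board.ball_diameter_mm / 2 + 30.0
            if i == 0:
                # Initial reach from the start marker to the first ball.
                builder.segment(grasp_from, seg_unit, _APERTURE_HOLD)
                held = move.ball_id
            if move.ball_id != held:
                # Travel to the next ball, then transport it.
                builder.segment(grasp_from, seg_unit * 0.4, _APERTURE_OPEN)
                builder.segment(via, seg_unit * 0.3, _APERTURE_HOLD)
                builder.segment(grasp_to, seg_unit * 0.3, _APERTURE_HOLD)
                held = move.ball_id
            else:
                builder.segment(via, seg_unit * 0.5, _APERTURE_HOLD)
                builder.segment(grasp_to, seg_unit * 0.5, _APERTURE_HOLD)
        builder.segment(start, seg_unit, _APERTURE_START)
        # Absorb rounding drift: hold at start until the cue boundary.
        done = sum(len(c) for c in builder.chunks_ap)
        if done < t0 + n_trial:
            builder.hold((t0 + n_trial - done) / fs)
        gt.trial_spans.append(TrialWindow(t0, t0 + n_trial))
        if trial < n_trials - 1:
            builder.hold(rest_s)

    grip, aperture = builder.build()
    n = len(grip)
    expected = int(round((n_trials * trial_s + (n_trials - 1) * rest_s) * fs))
    assert n == expected, (n, expected)

    # Shared low-frequency hand jitter (copied by the imitator, so it does
    # not degrade coupling).
    for ax in range(3):
        grip[:, ax] += _smooth_noise(n, fs, 5.0, jitter_mm, rng)

    ux = np.array([1.0, 0.0, 0.0])
    index = grip + (aperture[:, None] / 2) * ux
    thumb = grip - (aperture[:, None] / 2) * ux
    wrist = grip + _WRIST_OFFSET
    little = grip + _LITTLE_OFFSET
    shoulder = _SHOULDER_BASE + np.column_stack(
        [_smooth_noise(n, fs, 1.0, 2.0, rng) for _ in range(3)]
    )
    elbow = _two_link_elbow(shoulder, wrist)
    t = np.arange(n) / fs
    head = _HEAD_BASE + np.column_stack(
        [15.0 * np.sin(2 * np.pi * 0.03 * t + float(rng.uniform(0, 2 * np.pi)))
         + _smooth_noise(n, fs, 0.5, 3.0, rng) for _ in range(3)]
    )

    positions = {
        "head": head, "shoulder": shoulder, "elbow": elbow, "wrist": wrist,
        "thumb": thumb, "index": index, "little": little,
    }
    columns: dict[str, np.ndarray] = {}
    for tracker in TRACKERS:
        for ax, dof in enumerate(("x", "y", "z")):
            columns[f"{tracker}_{dof}"] = positions[tracker][:, ax]
    columns.update(_orientation_channels(positions, fs, rng))

    data = pd.DataFrame({c: columns[c] for c in CHANNELS})
    rec = Recording(
        person_id=person_id,
        role=Role.actor,
        feedback=Feedback(feedback),
        difficulty=difficulty,
        data=data,
        start_point=start,
        sample_rate=fs,
    ).validate()

    # Motion-defined windows: runs where the index fingertip is >100 mm
    # from the start marker (what the segmenter is expected to recover).
    disp = np.linalg.norm(index - start[None, :], axis=1)
    gt.trial_windows = _runs_above(disp > 100.0, min_len=int(5 * fs))
    return rec, gt


def _runs_above(mask: np.ndarray, min_len: int) -> list[TrialWindow]:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return [TrialWindow(int(s), int(e)) for s, e in zip(starts, ends)
            if e - s > min_len]


def synth_imitator(
    actor: Recording,
    true_lag_s: float,
    noise_sd: float,
    gain: float,
    rng: np.random.Generator,
    *,
    noise_cutoff_hz: float = 8.0,
    person_id: str = "imitator",
) -> tuple[Recording, GroundTruth]:
    """Derive an imitator recording as a lagged, noisy copy of the actor.

    Each channel is delayed by ``round(true_lag_s * fs)`` samples (edges
    padded with the rest posture, i.e. the boundary sample), scaled by
    ``gain`` about its mean, and perturbed by low-passed Gaussian noise of
    SD ``noise_sd`` so the noise has kinematic plausibility.
    """
    fs = actor.sample_rate
    if abs(true_lag_s) > 5.0:
        raise ValueError("|true_lag_s| must be <= 5 s (the analysis window)")
    k = int(round(true_lag_s * fs))
    n = actor.n_samples
    if abs(k) >= n:
        raise ValueError("lag exceeds the recording length")
    out = {}
    for col in CHANNELS:
        x = actor.channel(col)
        if k >= 0:
            shifted = np.concatenate([np.full(k, x[0]), x[: n - k]])
        else:
            shifted = np.concatenate([x[-k:], np.full(-k, x[-1])])
        if gain == 1.0:
            y = shifted
        else:
            y = x.mean() + gain * (shifted - x.mean())
        if noise_sd > 0:
            # Orientation channels are degrees with ~10x smaller amplitude
            # than positions (mm); scale their noise accordingly.
            sd = noise_sd * (0.1 if col.split("_", 1)[1] in ORIENTATION_DOFS else 1.0)
            y = y + _smooth_noise(n, fs, noise_cutoff_hz, sd, rng)
        out[col] = y
    rec = Recording(
        person_id=person_id,
        role=Role.imitator,
        feedback=actor.feedback,
        difficulty=actor.difficulty,
        data=pd.DataFrame(out),
        start_point=actor.start_point.copy(),
        sample_rate=fs,
    ).validate()
    gt = GroundTruth(true_lag_s=true_lag_s, coupling_noise_sd=noise_sd, gain=gain)
    return rec, gt


def inject_spikes(
    rec: Recording,
    n_per_series: int,
    amplitude: float | dict[str, float],
    rng: np.random.Generator,
    *,
    min_gap: int = 5,
) -> tuple[Recording, dict[str, np.ndarray]]:
    """Add single-sample offsets emulating electromagnetic artifacts.

    Spike positions are at least ``min_gap`` samples from the series edges
    and from each other.  Returns the spiked recording and the per-channel
    index ledger.
    """
    n = rec.n_samples
    lo, hi = min_gap, n - min_gap  # exclusive hi
    if n_per_series < 0:
        raise ValueError("n_per_series must be non-negative")
    if n_per_series > 0 and (hi - lo) < n_per_series * min_gap:
        raise ValueError("too many spikes for the spacing constraint")
    out = rec.copy()
    ledger: dict[str, np.ndarray] = {}
    for col in CHANNELS:
        idx: list[int] = []
        attempts = 0
        while len(idx) < n_per_series:
            cand = int(rng.integers(lo, hi))
            if all(abs(cand - j) >= min_gap for j in idx):
                idx.append(cand)
            attempts += 1
            if attempts > 1000 * max(n_per_series, 1):
                raise ValueError("could not place spikes with required spacing")
        idx_arr = np.sort(np.array(idx, dtype=int))
        amp = amplitude[col] if isinstance(amplitude, dict) else float(amplitude)
        if n_per_series > 0 and amp <= 0:
            raise ValueError("spike amplitude must be positive")
        vals = out.data[col].to_numpy()
        vals[idx_arr] += amp
        out.data[col] = vals
        ledger[col] = idx_arr
    return out, ledger
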
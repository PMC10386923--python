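"""Session configuration: task geometry, display/recording rates, and analysis windows.

All distances are millimetres, all times seconds unless a field name carries an
explicit ``_ms`` suffix.  The coordinate frame has its origin at the starting
point, x positive rightward (the direction of target motion) and y positive
away from the participant; "lateral" always means x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class SessionConfig:
    """Constants of the interception task and of the kinematic analysis.

    The defaults describe a target that appears 30 cm to the left of and
    20 cm beyond the starting point, moves rightward at 50 cm/s, and is
    jittered (or the cursor offset is jittered) by a +/-2.5 mm lateral
    random-walk step on every 60 Hz display frame, while the finger is
    tracked at 500 Hz.

    Parameters
    ----------
    frame_rate:
        Display frame rate in Hz.  One jitter step is applied per frame.
    sample_rate:
        Motion-capture sampling rate of the finger position, Hz.
    step_amplitude:
        Size of each random-walk jitter step, mm.
    target_speed:
        Rightward target speed, mm/s.
    target_start:
        Target position at appearance, (x, y) mm relative to the start point.
    target_diameter, cursor_diameter, start_diameter:
        Disc diameters, mm.  A trial counts as a hit when the interpolated
        cursor centre ever falls within the target disc (<= target radius).
    max_trial_duration:
        Hard cap on simulated/recorded trial duration, s.
    near_path_threshold:
        If the finger never crosses the target's path, the movement end is
        taken at the maximal distance from the start as long as the finger
        came within this distance of the path, mm; otherwise the trial is
        excluded.
    latency_floor_ms:
        Minimum visuomotor delay, ms.  Steps closer than this to the end of
        the movement cannot have evoked a response and are not analysed
        (strictly more than this value before the end is required).
    response_window_ms:
        How long after a selected step the response curve is followed, ms.
    savgol_window_ms:
        Width of the centred window for the local-polynomial (Savitzky-Golay)
        acceleration estimate, ms.
    savgol_polyorder:
        Order of the local polynomial; 2 yields simultaneous smoothing and
        double differentiation.
    """

    frame_rate: float = 60.0
    sample_rate: float = 500.0
    step_amplitude: float = 2.5
    target_speed: float = 500.0
    target_start: tuple[float, float] = (-300.0, 200.0)
    target_diameter: float = 27.0
    cursor_diameter: float = 10.0
    start_diameter: float = 20.0
    max_trial_duration: float = 1.5
    near_path_threshold: float = 20.0
    latency_floor_ms: float = 100.0
    response_window_ms: float = 250.0
    savgol_window_ms: float = 40.0
    savgol_polyorder: int = 2

    def __post_init__(self) -> None:
        positive = [
            "frame_rate",
            "sample_rate",
            "step_amplitude",
            "target_speed",
            "target_diameter",
            "cursor_diameter",
            "start_diameter",
            "max_trial_duration",
            "near_path_threshold",
            "latency_floor_ms",
            "response_window_ms",
            "savgol_window_ms",
        ]
        for name in positive:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"SessionConfig.{name} must be strictly positive, got {value!r}")
        if len(self.target_start) != 2:
            raise ValueError("target_start must be a 2-D point (x, y)")
        n_window = self.savgol_window_samples
        if not 0 <= self.savgol_polyorder < n_window:
            raise ValueError(
                f"savgol_polyorder ({self.savgol_polyorder}) must be smaller than the "
                f"number of samples in the window ({n_window})"
            )
        if not self.latency_floor_ms < self.response_window_ms:
            raise ValueError("latency_floor_ms must be smaller than response_window_ms")

    # -- derived quantities ------------------------------------------------

    @property
    def frame_dt(self) -> float:
        """Time between display frames, s."""
        return 1.0 / self.frame_rate

    @property
    def sample_dt(self) -> float:
        """Time between finger-position samples, s."""
        return 1.0 / self.sample_rate

    @property
    def target_radius(self) -> float:
        return self.target_diameter / 2.0

    @property
    def path_y(self) -> float:
        """y coordinate of the target's (straight, horizontal) path, mm."""
        return float(self.target_start[1])

    @property
    def latency_floor(self) -> float:
        return self.latency_floor_ms / 1000.0

    @property
    def response_window(self) -> float:
        return self.response_window_ms / 1000.0

    @property
    def savgol_window(self) -> float:
        return self.savgol_window_ms / 1000.0

    @property
    def savgol_window_samples(self) -> int:
        """Samples in the centred estimation window (odd: centre +/- half-span)."""
        half = int(round(self.savgol_window / 2.0 * self.sample_rate))
        return 2 * half + 1

    @property
    def jitter_speed(self) -> float:
        """Speed equivalent of one step per frame, mm/s (2.5 mm at 60 Hz -> 150)."""
        return self.step_amplitude * self.frame_rate

    def replace(self, **changes) -> "SessionConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(changes)
        return SessionConfig(**current)
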
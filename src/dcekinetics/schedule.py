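"""Acquisition timing for a serial DCE-MRI protocol.

The protocol modelled here acquires a fixed number of pre-contrast
repetitions of a dynamic sequence, then repeats the same sequence
back-to-back after contrast-agent injection, starting at a fixed delay
after the start of the injection.  Each repetition takes ``t_acq``
seconds, so post-contrast scan *n* (1-based) completes at

    T_n = t_offset + n * t_acq        [seconds since injection start]

Completion times are the time axis used by every kinetic formula; the
signal itself is simulated at mid-acquisition time (see
:mod:`dcekinetics.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ScanSchedule", "scan_completion_time"]


@dataclass(frozen=True)
class ScanSchedule:
    """Timing of one dynamic acquisition run.

    Parameters
    ----------
    n_pre : int
        Pre-contrast repetitions of the dynamic sequence (default 2).
    n_post : int
        Post-contrast repetitions (default 39).
    t_acq : float
        Acquisition time of one repetition, seconds (default 29).
    t_offset : float
        Delay from injection start to the start of the first
        post-contrast repetition, seconds (default 50).
    """

    n_pre: int = 2
    n_post: int = 39
    t_acq: float = 29.0
    t_offset: float = 50.0

    def __post_init__(self) -> None:
        if self.n_pre < 1:
            raise ValueError("n_pre must be >= 1")
        if self.n_post < 3:
            raise ValueError("n_post must be >= 3")
        if self.t_acq <= 0:
            raise ValueError("t_acq must be positive")
        if self.t_offset < 0:
            raise ValueError("t_offset must be non-negative")

    def completion_time(self, n: int) -> float:
        """Completion time (s since injection start) of post-scan ``n``."""
        return scan_completion_time(n, self)

    def mid_time(self, n: int) -> float:
        """Mid-acquisition time (s since injection start) of post-scan ``n``."""
        if not 1 <= n <= self.n_post:
            raise ValueError(
                f"post-scan index must be in 1..{self.n_post}, got {n}"
            )
        return self.t_offset + (n - 0.5) * self.t_acq

    @property
    def completion_times(self):
        """Completion times T_1..T_n_post as a list (seconds)."""
        return [self.completion_time(n) for n in range(1, self.n_post + 1)]

    @property
    def n_scans(self) -> int:
        return self.n_pre + self.n_post


def scan_completion_time(n: int, schedule: ScanSchedule | None = None) -> float:
    """Time from injection start to completion of post-contrast scan ``n``.

    With the default schedule, scan 1 completes at 79 s and scan 39 at
    1181 s.  Pre-contrast scans (slot 0) carry no post-injection time and
    are rejected.
    """
    if schedule is None:
        schedule = ScanSchedule()
    if not 1 <= n <= schedule.n_post:
        raise ValueError(
            f"post-scan index must be in 1..{schedule.n_post}, got {n} "
            "(pre-contrast slots have no post-injection time)"
        )
    return schedule.t_offset + n * schedule.t_acq
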
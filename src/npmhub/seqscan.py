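"""Nucleolar localization signal (NoLS) detection by sliding-window charge scoring.

NoLS motifs are short stretches rich in lysines and arginines arranged in
variably spaced clusters within disordered regions.  The scan slides a
13-residue window along the sequence and assigns each window the score

    score = min(1, n_basic / s_max)

where n_basic counts K/R (histidine excluded by default, configurable) and
s_max (default 6) saturates the score.  Windows scoring above the threshold
(default 0.8) are merged by coordinate union into putative NoLS segments.
This is a transparent charge-count surrogate for neural-network NoLS
predictors: it reproduces the presence/absence calls on the peptides this
package studies, not any particular predictor's numeric scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ScanConfig",
    "ScanProfile",
    "NolsSegment",
    "count_basic",
    "basic_clusters",
    "scan_nols",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ScanConfig:
    """Window scan parameters (1-based inclusive output coordinates)."""

    window: int = 13
    step: int = 1
    threshold: float = 0.8
    s_max: int = 6
    basic_set: frozenset = frozenset({"K", "R"})
    allow_unknown: bool = False  # pass 'X' (and other unknowns) through as neutral

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")
        if self.s_max < 1:
            raise ValueError("s_max must be >= 1")


@dataclass(frozen=True)
class NolsSegment:
    """A putative NoLS: union of overlapping above-threshold windows."""

    start: int  # 1-based inclusive
    end: int
    peak_score: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end must be >= start")


@dataclass
class ScanProfile:
    """Per-window scores for one sequence; coordinates 1-based inclusive."""

    sequence_id: str
    starts: list = field(default_factory=list)
    ends: list = field(default_factory=list)
    scores: list = field(default_factory=list)
    truncated: bool = False  # sequence shorter than the window


def _check_sequence(seq: str, basic_set, allow_unknown: bool) -> None:
    known = AMINO_ACIDS | set(basic_set)
    for i, ch in enumerate(seq):
        if ch not in known and not allow_unknown:
            raise ValueError(f"unknown residue {ch!r} at position {i + 1}")


def count_basic(seq: str, basic_set=frozenset({"K", "R"}),
                allow_unknown: bool = False) -> int:
    """Number of positively charged (basic-set) residues in ``seq``."""
    seq = seq.upper()
    _check_sequence(seq, basic_set, allow_unknown)
    return sum(1 for ch in seq if ch in basic_set)


def basic_clusters(seq: str, min_run: int = 2,
                   basic_set=frozenset({"K", "R"}),
                   allow_unknown: bool = False) -> list[NolsSegment]:
    """Maximal runs of >= min_run consecutive basic residues, as 1-based spans."""
    seq = seq.upper()
    _check_sequence(seq, basic_set, allow_unknown)
    spans = []
    run_start = None
    for i, ch in enumerate(seq + "!"):  # sentinel terminates the last run
        if ch in basic_set:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_run:
                spans.append(NolsSegment(run_start + 1, i, 1.0))
            run_start = None
    return spans


def scan_nols(seq: str, config: ScanConfig = ScanConfig(),
              sequence_id: str = "seq") -> tuple[ScanProfile, list[NolsSegment]]:
    """Sliding-window charge scan; returns the profile and merged segments.

    Sequences shorter than the window are scored as one truncated window
    covering the whole sequence and flagged on the profile.
    """
    seq = seq.upper()
    if len(seq) < 1:
        raise ValueError("sequence must be non-empty")
    _check_sequence(seq, config.basic_set, config.allow_unknown)

    profile = ScanProfile(sequence_id=sequence_id)
    if len(seq) < config.window:
        windows = [(1, len(seq))]
        profile.truncated = True
    else:
        windows = [
            (s + 1, s + config.window)
            for s in range(0, len(seq) - config.window + 1, config.step)
        ]
    for start, end in windows:
        n_basic = sum(1 for ch in seq[start - 1:end] if ch in config.basic_set)
        score = min(1.0, n_basic / config.s_max)
        profile.starts.append(start)
        profile.ends.append(end)
        profile.scores.append(score)

    # merge overlapping/adjacent above-threshold windows into segments
    segments: list[NolsSegment] = []
    cur = None  # [start, end, peak]
    for start, end, score in zip(profile.starts, profile.ends, profile.scores):
        if score > config.threshold:
            if cur is not None and start <= cur[1] + 1:
                cur[1] = max(cur[1], end)
                cur[2] = max(cur[2], score)
            else:
                if cur is not None:
                    segments.append(NolsSegment(cur[0], cur[1], cur[2]))
                cur = [start, end, score]
    if cur is not None:
        segments.append(NolsSegment(cur[0], cur[1], cur[2]))
    return profile, segments
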
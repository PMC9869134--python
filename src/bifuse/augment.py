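"""Sliding-window trial augmentation and leakage-aware splitting.

Two training strategies expand the 10-s trials into 3-s sub-trials:
strategy A uses non-overlapping windows (step 3 s, three sub-trials per
trial); strategy B slides with a 1-s step (eight overlapping sub-trials
per trial).  Splitting is performed over parent trials by default so that
overlapping sub-trials of one trial never straddle the train/test boundary;
the literal shuffle-then-split over sub-trials is available for strategy-A
replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ChromophoreEpoch, Epoch, SubTrial

WINDOW_S = 3.0
STEP_A_S = 3.0
STEP_B_S = 1.0


@dataclass
class WindowPlan:
    """A sliding-window layout over the cue-locked trial span."""

    window_s: float = WINDOW_S
    step_s: float = STEP_B_S
    origin_s: float = 0.0
    span_s: float = 10.0

    def __post_init__(self) -> None:
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")
        if self.window_s > self.span_s:
            raise ValueError(
                f"window ({self.window_s} s) longer than available span ({self.span_s} s)"
            )

    @property
    def n_windows(self) -> int:
        return int(np.floor((self.span_s - self.window_s) / self.step_s)) + 1

    def starts(self) -> list[float]:
        return [self.origin_s + i * self.step_s for i in range(self.n_windows)]


def _cut(epoch: Epoch, start_s: float, window_s: float) -> Epoch:
    i0 = int(round((start_s - epoch.t_start_s) * epoch.sample_rate_hz))
    n = int(round(window_s * epoch.sample_rate_hz))
    if i0 < 0 or i0 + n > epoch.n_samples:
        raise ValueError(f"window [{start_s}, {start_s + window_s}) s outside epoch")
    return epoch.replace(data=epoch.data[:, i0 : i0 + n], t_start_s=start_s)


def slide_windows(
    trial_pair: tuple[Epoch, Epoch],
    plan: WindowPlan,
) -> list[SubTrial]:
    """Cut both modality epochs of one trial into identically-timed windows.

    ``trial_pair`` is (eeg_epoch, fnirs_epoch); the fNIRS member is one
    chromophore plane already resampled to the EEG rate.
    """
    eeg, fnirs = trial_pair
    if eeg.parent_trial_id != fnirs.parent_trial_id:
        raise ValueError("modalities belong to different parent trials")
    out = []
    for i, start in enumerate(plan.starts()):
        out.append(
            SubTrial(
                eeg=_cut(eeg, start, plan.window_s),
                fnirs=_cut(fnirs, start, plan.window_s),
                parent_trial_id=eeg.parent_trial_id,
                window_index=i,
                window_start_s=start,
            )
        )
    return out


def _pick_chromophore(fnirs: Epoch | ChromophoreEpoch, chromophore: str) -> Epoch:
    if isinstance(fnirs, ChromophoreEpoch):
        return getattr(fnirs, chromophore)
    return fnirs


def _apply_strategy(
    trials: list[tuple[Epoch, Epoch | ChromophoreEpoch]],
    step_s: float,
    chromophore: str,
) -> list[SubTrial]:
    out = []
    for eeg, fnirs in trials:
        fn = _pick_chromophore(fnirs, chromophore)
        plan = WindowPlan(window_s=WINDOW_S, step_s=step_s, origin_s=eeg.t_start_s,
                          span_s=eeg.duration_s)
        out.extend(slide_windows((eeg, fn), plan))
    return out


def strategy_a(
    trials: list[tuple[Epoch, Epoch | ChromophoreEpoch]], chromophore: str = "hbo"
) -> list[SubTrial]:
    """Non-overlapping 3-s windows, step 3 s: three sub-trials per 10-s trial."""
    return _apply_strategy(trials, STEP_A_S, chromophore)


def strategy_b(
    trials: list[tuple[Epoch, Epoch | ChromophoreEpoch]], chromophore: str = "hbo"
) -> list[SubTrial]:
    """Overlapping 3-s windows, step 1 s: eight sub-trials per 10-s trial."""
    return _apply_strategy(trials, STEP_B_S, chromophore)


def grouped_split(
    subtrials: list[SubTrial],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[SubTrial], list[SubTrial]]:
    """Split over parent trials so no trial contributes to both sides.

    The test side receives ``floor(test_fraction * n_parents)`` whole parent
    trials (at least one).  Shuffling is seeded.
    """
    parents = sorted({s.parent_trial_id for s in subtrials})
    if len(parents) < 2:
        raise ValueError("grouped split needs at least 2 parent trials")
    rng = np.random.default_rng(seed)
    rng.shuffle(parents)
    n_test = max(1, int(len(parents) * test_fraction))
    test_ids = set(parents[:n_test])
    train = [s for s in subtrials if s.parent_trial_id not in test_ids]
    test = [s for s in subtrials if s.parent_trial_id in test_ids]
    return train, test


def per_subtrial_split(
    subtrials: list[SubTrial],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[SubTrial], list[SubTrial]]:
    """Literal shuffle-then-split over sub-trials (strategy-A replication).

    Sibling sub-trials of one parent trial may land on both sides; use
    :func:`grouped_split` whenever leakage matters.
    """
    if len(subtrials) < 2:
        raise ValueError("need at least 2 sub-trials to split")
    order = np.random.default_rng(seed).permutation(len(subtrials))
    n_test = max(1, int(len(subtrials) * test_fraction))
    test_idx = set(order[:n_test].tolist())
    train = [s for i, s in enumerate(subtrials) if i not in test_idx]
    test = [s for i, s in enumerate(subtrials) if i in test_idx]
    return train, test
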
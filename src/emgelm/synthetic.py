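"""Seeded synthetic sEMG trial generation.

Emulates the cue-driven acquisition protocol used by multi-movement sEMG
databases: a subject performs ``n_movements`` distinct upper-limb movements,
each repeated ``n_repetitions`` times in sequential or random order, with rest
between bursts.  Four stock protocol layouts (assays A-D) mirror the common
6/10-repetition sequential/random designs.

The signal model is amplitude-modulated zero-mean Gaussian noise — the
standard sEMG surrogate: during a movement burst of class ``c`` each channel
``k`` records baseline instrumentation noise plus an extra white-noise term
scaled by ``snr * activation[c, k]`` and a Gaussian amplitude envelope, which
reproduces the incremental recruitment profile of motor-unit action
potentials.  Stimulation (cue) labels are shifted relative to the true muscle
activity by a per-burst reaction-time delay, so the label-refinement stage has
a realistic misalignment to correct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("emgelm")

REST_CLASS = 0

#: Assay code -> (n_repetitions, order)
_ASSAY_LAYOUTS = {
    "A": (6, "sequential"),
    "B": (10, "sequential"),
    "C": (6, "random"),
    "D": (10, "random"),
}


class UnknownAssayError(ValueError):
    """Raised for an assay code outside A-D."""


@dataclass(frozen=True)
class Protocol:
    """Acquisition-protocol layout: what the subject is asked to perform."""

    n_movements: int = 17
    n_repetitions: int = 6
    order: str = "sequential"  # or "random"
    movement_duration_s: float = 5.0
    rest_duration_s: float = 3.0
    sample_rate_hz: float = 2000.0
    n_channels: int = 12

    def __post_init__(self) -> None:
        if self.n_movements < 1:
            raise ValueError("n_movements must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.movement_duration_s <= 0 or self.rest_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.order not in ("sequential", "random"):
            raise ValueError(f"order must be 'sequential' or 'random', got {self.order!r}")


@dataclass(frozen=True)
class SubjectModel:
    """Subject-specific signal characteristics.

    ``activation[c - 1, k]`` is the nonnegative gain of movement class ``c``
    (1-based) on channel ``k``; distinct classes must have distinct rows so the
    classes are separable in principle.  ``snr`` scales movement modulation
    relative to ``baseline_noise_sd``; ``snr = 0`` together with an all-zero
    activation matrix is accepted as a degenerate pure-noise model for
    diagnostics.  Reaction-time delays are drawn per burst, uniformly in
    ``reaction_delay_range_ms``.
    """

    activation: np.ndarray
    baseline_noise_sd: float = 1.0
    snr: float = 3.0
    reaction_delay_range_ms: tuple[float, float] = (60.0, 300.0)
    seed: int = 0

    def __post_init__(self) -> None:
        act = np.asarray(self.activation, dtype=float)
        object.__setattr__(self, "activation", act)
        if act.ndim != 2:
            raise ValueError("activation must be a (n_movements, n_channels) matrix")
        if np.any(act < 0):
            raise ValueError("activation gains must be nonnegative")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        if self.baseline_noise_sd <= 0:
            raise ValueError("baseline_noise_sd must be positive")
        lo, hi = self.reaction_delay_range_ms
        if not (0 <= lo <= hi):
            raise ValueError("reaction_delay_range_ms must satisfy 0 <= low <= high")
        if np.any(act):  # all-zero matrix: degenerate no-signal model, allowed
            uniq = np.unique(act, axis=0)
            if uniq.shape[0] != act.shape[0]:
                raise ValueError("distinct classes must have distinct activation rows")

    @classmethod
    def random(
        cls,
        n_movements: int = 17,
        n_channels: int = 12,
        seed: int = 0,
        *,
        baseline_noise_sd: float = 1.0,
        snr: float = 3.0,
        reaction_delay_range_ms: tuple[float, float] = (60.0, 300.0),
    ) -> "SubjectModel":
        """Draw a plausible subject: each movement engages 4-9 of the channels
        (muscles) with gains in [0.3, 1.0], all other gains zero."""
        rng = np.random.default_rng(seed)
        act = np.zeros((n_movements, n_channels))
        lo, hi = min(4, n_channels), min(9, n_channels)
        for c in range(n_movements):
            n_active = int(rng.integers(lo, hi + 1))
            chans = rng.choice(n_channels, size=n_active, replace=False)
            act[c, chans] = rng.uniform(0.3, 1.0, size=n_active)
        return cls(
            activation=act,
            baseline_noise_sd=baseline_noise_sd,
            snr=snr,
            reaction_delay_range_ms=reaction_delay_range_ms,
            seed=seed,
        )


@dataclass
class EmgRecording:
    """A multi-channel recording plus its per-sample label streams.

    ``signal`` is channels x samples.  ``stim_labels`` follow the stimulation
    timestamps (what a cue-driven acquisition records); ``true_labels``, when
    known (synthetic data), mark the actual muscle-activity support.
    ``refined_labels`` is filled in by the GLR relabeling stage.  Class 0 is
    rest; movement classes are 1..n_movements.
    """

    signal: np.ndarray
    sample_rate_hz: float
    stim_labels: np.ndarray
    true_labels: np.ndarray | None = None
    repetition_ids: np.ndarray | None = None
    refined_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.stim_labels = np.asarray(self.stim_labels, dtype=np.int64)
        if self.signal.shape[1] != self.stim_labels.shape[0]:
            raise ValueError(
                f"signal has {self.signal.shape[1]} samples but stim_labels has "
                f"{self.stim_labels.shape[0]} entries"
            )
        for name in ("true_labels", "refined_labels", "repetition_ids"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.int64)
                if v.shape[0] != self.signal.shape[1]:
                    raise ValueError(f"{name} length does not match signal")
                setattr(self, name, v)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def labels(self, source: str = "stim") -> np.ndarray:
        """Return one of the label streams: 'stim', 'true' or 'refined'."""
        if source == "stim":
            return self.stim_labels
        if source == "true":
            if self.true_labels is None:
                raise ValueError("recording has no true_labels")
            return self.true_labels
        if source == "refined":
            if self.refined_labels is None:
                raise ValueError("recording has no refined_labels; run glr_relabel first")
            return self.refined_labels
        raise ValueError(f"unknown label source {source!r}")


def make_protocol(assay: str) -> Protocol:
    """Build the stock protocol for assay code A, B, C or D.

    A/B: 6/10 repetitions in sequential order; C/D: the same counts in random
    order.  All other fields at defaults (17 movements, 12 channels, 2 kHz).
    """
    try:
        reps, order = _ASSAY_LAYOUTS[assay]
    except (KeyError, TypeError):
        raise UnknownAssayError(
            f"unknown assay code {assay!r}; expected one of {sorted(_ASSAY_LAYOUTS)}"
        ) from None
    return Protocol(n_repetitions=reps, order=order)


def _movement_sequence(protocol: Protocol, rng: np.random.Generator) -> np.ndarray:
    """Class id for each burst, in execution order."""
    base = np.arange(1, protocol.n_movements + 1)
    blocks = []
    for _ in range(protocol.n_repetitions):
        if protocol.order == "random":
            blocks.append(rng.permutation(base))
        else:
            blocks.append(base.copy())
    return np.concatenate(blocks)


def generate_trial(protocol: Protocol, subject: SubjectModel) -> EmgRecording:
    """Simulate one trial of the given protocol for the given subject.

    Timeline: rest, then for each burst movement followed by rest.  During a
    burst of class ``c`` channel ``k`` records::

        baseline_noise + snr * activation[c-1, k] * envelope(t) * white_noise

    with a Gaussian envelope (sigma = duration / 3) spanning the burst, peak 1
    at the burst centre.  ``true_labels`` mark the burst support;
    ``stim_labels`` are the same stream with each burst shifted later by a
    per-burst delay drawn uniformly from ``reaction_delay_range_ms``.
    Deterministic for a fixed ``subject.seed``.
    """
    if subject.activation.shape != (protocol.n_movements, protocol.n_channels):
        raise ValueError(
            f"activation shape {subject.activation.shape} does not match protocol "
            f"({protocol.n_movements}, {protocol.n_channels})"
        )
    fs = protocol.sample_rate_hz
    move_n = int(round(protocol.movement_duration_s * fs))
    rest_n = int(round(protocol.rest_duration_s * fs))
    if move_n < 1 or rest_n < 1:
        raise ValueError("protocol durations are too short for the sample rate")

    rng = np.random.default_rng(subject.seed)
    seq = _movement_sequence(protocol, rng)
    n_bursts = seq.size
    total = rest_n + n_bursts * (move_n + rest_n)

    signal = rng.normal(0.0, subject.baseline_noise_sd, size=(protocol.n_channels, total))
    true_labels = np.zeros(total, dtype=np.int64)
    stim_labels = np.zeros(total, dtype=np.int64)
    repetition_ids = np.zeros(total, dtype=np.int64)

    # Gaussian activation envelope truncated at the burst support: sigma =
    # duration/2 leaves ~61% of peak modulation at the edges, so switching the
    # muscle on/off is a genuine amplitude change point while the within-burst
    # profile waxes and wanes with the motor-unit recruitment bell shape.  A
    # profile decaying smoothly to zero would make the support edge
    # statistically unidentifiable for any boundary estimator.
    t = np.arange(move_n)
    centre = (move_n - 1) / 2.0
    sigma = move_n / 2.0
    envelope = np.exp(-0.5 * ((t - centre) / sigma) ** 2)

    lo, hi = subject.reaction_delay_range_ms
    pos = rest_n
    prev_end = 0
    for i, cls in enumerate(seq):
        start, end = pos, pos + move_n
        gains = subject.snr * subject.activation[cls - 1]  # (channels,)
        burst = rng.normal(0.0, 1.0, size=(protocol.n_channels, move_n))
        signal[:, start:end] += gains[:, None] * envelope[None, :] * burst
        true_labels[start:end] = cls

        delay = int(round(rng.uniform(lo, hi) / 1000.0 * fs))
        stim_labels[min(start + delay, total): min(end + delay, total)] = cls

        rep = i // protocol.n_movements + 1
        repetition_ids[prev_end:end] = rep  # preceding rest inherits this burst's repetition
        prev_end = end
        pos = end + rest_n
    repetition_ids[prev_end:] = protocol.n_repetitions  # trailing rest

    return EmgRecording(
        signal=signal,
        sample_rate_hz=fs,
        stim_labels=stim_labels,
        true_labels=true_labels,
        repetition_ids=repetition_ids,
    )
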
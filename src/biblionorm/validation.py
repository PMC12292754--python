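"""Precision-validation harness for the synonym detector.

Mirrors the expert-review protocol: draw a stratified random sample of
detected synonym pairs (strata = detection tiers, allocation proportional
to tier sizes), have several raters label each pair correct/incorrect,
and score precision under the unanimity rule — a pair counts as correct
only when every rater agrees it is.
"""

from __future__ import annotations

import csv
import io
import json
import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .term_normalize import MatchEvidence

__all__ = [
    "ValidationConfig",
    "SampledPair",
    "ValidationReport",
    "stratified_sample",
    "proportional_allocation",
    "compute_precision",
    "write_sample",
    "read_labels",
]


@dataclass(frozen=True)
class ValidationConfig:
    n_pairs: int = 300
    n_raters: int = 3
    pass_threshold: float = 0.90
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if not (0.0 < self.pass_threshold <= 1.0):
            raise ValueError("pass_threshold must be in (0, 1]")


@dataclass(frozen=True)
class SampledPair:
    term_a: str
    term_b: str
    tier: str

    @property
    def pair_id(self) -> str:
        return f"{self.term_a}|{self.term_b}"


@dataclass
class ValidationReport:
    n_sampled: int
    n_unanimously_correct: int
    pass_threshold: float

    @property
    def precision(self) -> float:
        return self.n_unanimously_correct / self.n_sampled

    @property
    def passed(self) -> bool:
        return self.precision >= self.pass_threshold

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_sampled": self.n_sampled,
                "n_unanimously_correct": self.n_unanimously_correct,
                "precision": self.precision,
                "passed": self.passed,
            },
            indent=2,
        )


def proportional_allocation(stratum_sizes: Mapping[str, int], n: int) -> dict[str, int]:
    """Largest-remainder allocation of ``n`` draws across strata.

    Quotas are proportional to stratum sizes; integer parts are assigned
    first and the leftover draws go to the largest fractional remainders
    (ties broken by stratum name for determinism).  No stratum is ever
    allocated more than its size.
    """
    total = sum(stratum_sizes.values())
    if total <= 0:
        raise ValueError("cannot allocate over empty strata")
    n = min(n, total)
    quotas = {s: n * size / total for s, size in stratum_sizes.items()}
    alloc = {s: int(q) for s, q in quotas.items()}
    leftover = n - sum(alloc.values())
    remainders = sorted(
        stratum_sizes, key=lambda s: (-(quotas[s] - alloc[s]), s)
    )
    for s in remainders[:leftover]:
        alloc[s] += 1
    return alloc


def stratified_sample(
    evidence: Sequence[MatchEvidence], config: ValidationConfig | None = None
) -> list[SampledPair]:
    """Draw a tier-stratified random sample of synonym-pair evidence.

    Sampling is without replacement within each stratum and fully
    deterministic per seed.  If fewer pairs exist than requested, all of
    them are returned.
    """
    config = config or ValidationConfig()
    if not evidence:
        raise ValueError("no evidence to sample from")
    by_tier: dict[str, list[MatchEvidence]] = {}
    for ev in evidence:
        by_tier.setdefault(ev.tier, []).append(ev)
    for tier in by_tier:
        by_tier[tier] = sorted(set(by_tier[tier]), key=lambda e: e.key)

    sizes = {tier: len(items) for tier, items in by_tier.items()}
    alloc = proportional_allocation(sizes, config.n_pairs)
    rng = random.Random(config.random_seed)
    sample: list[SampledPair] = []
    for tier in sorted(by_tier):
        chosen = rng.sample(by_tier[tier], alloc[tier])
        sample.extend(SampledPair(*ev.key, tier=tier) for ev in chosen)
    return sample


def compute_precision(
    sample: Sequence[SampledPair],
    labels_per_rater: Mapping[str, Mapping[str, bool]],
    config: ValidationConfig | None = None,
) -> ValidationReport:
    """Score unanimity precision over a labeled sample.

    ``labels_per_rater`` maps rater id -> {pair_id: correct?}.  Every
    sampled pair must be labeled by every rater; missing labels raise a
    ``ValueError`` listing the offending pairs.
    """
    config = config or ValidationConfig()
    if not sample:
        raise ValueError("empty sample: nothing to score")
    if len(labels_per_rater) != config.n_raters:
        raise ValueError(
            f"expected labels from {config.n_raters} raters, got {len(labels_per_rater)}"
        )
    missing = [
        f"{rater}:{pair.pair_id}"
        for rater, labels in labels_per_rater.items()
        for pair in sample
        if pair.pair_id not in labels
    ]
    if missing:
        raise ValueError(f"unlabeled pairs: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    unanimous = sum(
        1
        for pair in sample
        if all(labels[pair.pair_id] for labels in labels_per_rater.values())
    )
    return ValidationReport(
        n_sampled=len(sample),
        n_unanimously_correct=unanimous,
        pass_threshold=config.pass_threshold,
    )


def write_sample(sample: Sequence[SampledPair], stream: io.TextIOBase) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(["term_a", "term_b", "tier"])
    for pair in sample:
        writer.writerow([pair.term_a, pair.term_b, pair.tier])


def read_labels(stream: io.TextIOBase | Iterable[str]) -> dict[str, dict[str, bool]]:
    """Read rater labels: tab-separated ``pair_id  rater  correct|incorrect``."""
    labels: dict[str, dict[str, bool]] = {}
    reader = csv.reader(iter(stream), delimiter="\t")
    header = next(reader, None)
    if header is None:
        raise ValueError("empty labels file")
    for row in reader:
        if not row or not any(c.strip() for c in row):
            continue
        pair_id, rater, verdict = row[0], row[1], row[2].strip().lower()
        if verdict not in {"correct", "incorrect"}:
            raise ValueError(f"label must be correct/incorrect, got {verdict!r}")
        labels.setdefault(rater, {})[pair_id] = verdict == "correct"
    return labels
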
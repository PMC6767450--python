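"""Benchmark metrics: recall, mean false positives, causal-variant ranks.

For a suite of semisynthetic cases analyzed under their true inheritance
mode, three quantities summarize prioritizer performance per mode:

* recall — the fraction of cases whose causal variant appears anywhere in
  the reported candidate list ("solved" cases);
* mean false positives — the average number of reported candidates that
  are not the causal variant (for compound-het truths, both variants of
  the causal pair count as hits, not false positives);
* the distribution of causal-variant ranks (1-based; the better-ranked
  variant of a causal pair counts).  Missed cases are excluded from rank
  summaries rather than imputed.  Medians and quartiles use the
  lower-value convention (no interpolation), so a reported median is
  always an observed rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .prioritize import CandidateVariant
from .simulate import BenchmarkCase, SpikeInSpec

__all__ = ["EvaluationReport", "ModeSummary", "causal_rank", "evaluate_suite"]


def causal_rank(candidates: Sequence[CandidateVariant], truth: SpikeInSpec) -> int | None:
    """1-based rank of the causal variant; best of the pair for compound-het.

    ``None`` when the truth is absent from the candidate list.
    """
    truth_keys = truth.keys
    ranks = [c.rank for c in candidates if c.key in truth_keys]
    return min(ranks) if ranks else None


def _lower_quantile(sorted_vals: list[int], q: float) -> int:
    """Order statistic at the lower of the two bracketing positions."""
    idx = int(q * (len(sorted_vals) - 1))
    return sorted_vals[idx]


@dataclass
class ModeSummary:
    n_cases: int
    n_recovered: int
    mean_false_positives: float
    ranks: list[int] = field(default_factory=list)

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_cases if self.n_cases else 0.0

    @property
    def rank_summary(self) -> dict[str, int | None]:
        if not self.ranks:
            return {"q1": None, "median": None, "q3": None}
        s = sorted(self.ranks)
        return {
            "q1": _lower_quantile(s, 0.25),
            "median": _lower_quantile(s, 0.5),
            "q3": _lower_quantile(s, 0.75),
        }


@dataclass
class EvaluationReport:
    per_mode: dict[str, ModeSummary]

    @property
    def overall_recall(self) -> float:
        n = sum(m.n_cases for m in self.per_mode.values())
        r = sum(m.n_recovered for m in self.per_mode.values())
        return r / n if n else 0.0

    @property
    def overall_mean_false_positives(self) -> float:
        n = sum(m.n_cases for m in self.per_mode.values())
        if not n:
            return 0.0
        total = sum(m.mean_false_positives * m.n_cases for m in self.per_mode.values())
        return total / n

    def to_dict(self) -> dict:
        return {
            mode: {
                "n_cases": s.n_cases,
                "recall": s.recall,
                "mean_false_positives": s.mean_false_positives,
                **{f"rank_{k}": v for k, v in s.rank_summary.items()},
            }
            for mode, s in self.per_mode.items()
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [{"mode": m, **d} for m, d in self.to_dict().items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def evaluate_suite(
    cases: Sequence[tuple[BenchmarkCase, Sequence[CandidateVariant]]],
    gene_level: bool = False,
) -> EvaluationReport:
    """Aggregate recall, mean FP and rank distributions per inheritance mode.

    With ``gene_level=True`` false positives count distinct non-causal
    genes instead of variants (candidates without a gene each count once).
    """
    if not cases:
        raise ValueError("empty benchmark suite")
    buckets: dict[str, dict] = {}
    for case, candidates in cases:
        b = buckets.setdefault(
            case.mode.value, {"n": 0, "recovered": 0, "fp": 0, "ranks": []}
        )
        b["n"] += 1
        rank = causal_rank(candidates, case.truth)
        truth_keys = case.truth.keys
        if gene_level:
            fp_genes = {
                c.profile.gene or c.key for c in candidates if c.key not in truth_keys
            }
            fp = len(fp_genes)
        else:
            fp = sum(1 for c in candidates if c.key not in truth_keys)
        b["fp"] += fp
        if rank is not None:
            b["recovered"] += 1
            b["ranks"].append(rank)
    per_mode = {
        mode: ModeSummary(
            n_cases=b["n"],
            n_recovered=b["recovered"],
            mean_false_positives=b["fp"] / b["n"],
            ranks=b["ranks"],
        )
        for mode, b in buckets.items()
    }
    return EvaluationReport(per_mode=per_mode)


def plot_rank_distributions(report: EvaluationReport, path: str | Path) -> None:
    """Violin plot of causal-variant ranks per mode (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    modes = [m for m, s in report.per_mode.items() if s.ranks]
    data = [report.per_mode[m].ranks for m in modes]
    fig, ax = plt.subplots(figsize=(1.5 + 1.5 * len(modes), 4))
    if data:
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(modes) + 1), modes, rotation=20)
    ax.set_ylabel("causal variant rank")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
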
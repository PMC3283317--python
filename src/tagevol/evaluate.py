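"""Desk-scale replication of the simulation experiments.

Two experiments quantify how well the inference recovers duplications:

- *duplication counts*: simulate histories with a fixed total number ``x`` of
  duplications (half direct, half inverted) and 0%, 33% or 50% inversions,
  infer, and compare the inferred number of duplications (direct + inverted)
  against ``x``;
- *size distribution*: simulate the mixed design (4 tandem duplications, 1
  inverted duplication, 1 inversion and 1 deletion of size 1 or 2 per
  branch), infer, and compare the true and inferred duplication-size
  distributions (total-variation distance and per-size biases).

Only counts and size histograms are compared: equivalent optimal histories
abound, so matching individual inferred events to simulated ones would be
meaningless.  Replicates default to 20 to keep a full run at desk scale;
every replicate seed derives deterministically from the experiment seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tagevol.model import CostModel, DEFAULT_COSTS
from tagevol.multispecies import duplication_size_counts, infer_history
from tagevol.search import SearchParams
from tagevol.simulate import named_design, simulate_history

__all__ = [
    "ExperimentReport",
    "run_duplication_count_experiment",
    "run_size_distribution_experiment",
    "total_variation",
]


def _replicate_seed(seed: int, *parts: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    ss = np.random.SeedSequence([seed, *parts])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def total_variation(p: Counter, q: Counter) -> float:
    """Total-variation distance between two (unnormalised) histograms."""
    np_, nq = sum(p.values()), sum(q.values())
    if np_ == 0 or nq == 0:
        return 0.0 if np_ == nq else 1.0
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p[k] / np_ - q[k] / nq) for k in keys)


@dataclass
class ExperimentReport:
    """Per-replicate rows plus the experiment parameters; aggregates are
    always recomputed from the rows."""

    frame: pd.DataFrame
    params: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        header = "".join(
            f"# {k}={self.params[k]}\n" for k in sorted(self.params)
        )
        return header + self.frame.to_csv(sep="\t", index=False)

    def summary(self) -> dict:
        raise NotImplementedError


@dataclass
class CountReport(ExperimentReport):
    def summary(self) -> dict:
        g = self.frame.groupby("x")
        rel_err = (
            (self.frame.inferred_dups - self.frame.true_dups).abs()
            / self.frame.true_dups
        )
        return {
            "mean_inferred_by_x": dict(g.inferred_dups.mean()),
            "mean_relative_error": float(rel_err.mean()),
            "mean_bias": float(
                (self.frame.inferred_dups - self.frame.true_dups).mean()
            ),
            "valid_fraction": float(self.frame.valid.mean()),
        }


@dataclass
class SizeReport(ExperimentReport):
    def true_counts(self) -> Counter:
        return self._collect("true")

    def inferred_counts(self) -> Counter:
        return self._collect("inferred")

    def _collect(self, which: str) -> Counter:
        out: Counter = Counter()
        for _, row in self.frame.iterrows():
            for tok in str(row[f"{which}_sizes"]).split(","):
                if tok:
                    out[int(tok)] += 1
        return out

    def summary(self) -> dict:
        t, i = self.true_counts(), self.inferred_counts()
        nt, ni = sum(t.values()), sum(i.values())
        return {
            "tv_distance": total_variation(t, i),
            "size1_bias": i[1] / ni - t[1] / nt,
            "size2_bias": i[2] / ni - t[2] / nt,
            "valid_fraction": float(self.frame.valid.mean()),
        }


def run_duplication_count_experiment(
    leaves: int = 2,
    x_values: tuple = (2, 4, 6),
    inversion_fraction: float = 0.0,
    replicates: int = 20,
    seed: int = 0,
    costs: CostModel = DEFAULT_COSTS,
    params: SearchParams = SearchParams(),
) -> CountReport:
    """Duplication-count recovery under the fixed-total-duplications design."""
    rows = []
    for xi, x in enumerate(x_values):
        for rep in range(replicates):
            rep_seed = _replicate_seed(seed, 1, xi, rep)
            cfg = named_design(
                "fig6",
                leaves=leaves,
                x=x,
                inversion_fraction=inversion_fraction,
                seed=rep_seed,
            )
            history, state, gene_tree = simulate_history(cfg)
            result = infer_history(
                gene_tree, dict(state.orders), cfg.species_tree, costs, params
            )
            true_sizes = duplication_size_counts(history)
            inf_sizes = duplication_size_counts(result.history)
            rows.append(
                {
                    "x": x,
                    "replicate": rep,
                    "seed": rep_seed,
                    "true_dups": sum(true_sizes.values()),
                    "inferred_dups": sum(inf_sizes.values()),
                    "total_cost": result.total_cost,
                    "valid": bool(result.validation),
                }
            )
    frame = pd.DataFrame(rows)
    return CountReport(
        frame=frame,
        params={
            "experiment": "duplication_counts",
            "leaves": leaves,
            "x_values": ",".join(map(str, x_values)),
            "inversion_fraction": round(inversion_fraction, 4),
            "replicates": replicates,
            "seed": seed,
        },
    )


def run_size_distribution_experiment(
    leaves: int = 2,
    replicates: int = 20,
    seed: int = 0,
    costs: CostModel = DEFAULT_COSTS,
    params: SearchParams = SearchParams(),
) -> SizeReport:
    """Duplication-size-distribution recovery under the mixed design."""
    rows = []
    for rep in range(replicates):
        rep_seed = _replicate_seed(seed, 2, rep)
        cfg = named_design("fig7", leaves=leaves, seed=rep_seed)
        history, state, gene_tree = simulate_history(cfg)
        result = infer_history(
            gene_tree, dict(state.orders), cfg.species_tree, costs, params
        )
        t = duplication_size_counts(history)
        i = duplication_size_counts(result.history)
        rows.append(
            {
                "replicate": rep,
                "seed": rep_seed,
                "true_sizes": ",".join(
                    str(s) for s in sorted(t.elements())
                ),
                "inferred_sizes": ",".join(
                    str(s) for s in sorted(i.elements())
                ),
                "tv_distance": total_variation(t, i),
                "total_cost": result.total_cost,
                "valid": bool(result.validation),
            }
        )
    frame = pd.DataFrame(rows)
    return SizeReport(
        frame=frame,
        params={
            "experiment": "size_distribution",
            "leaves": leaves,
            "replicates": replicates,
            "seed": seed,
        },
    )


def plot_size_distribution(report: SizeReport, out_path: str) -> None:
    """Bar plot of true vs inferred duplication-size distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t, i = report.true_counts(), report.inferred_counts()
    sizes = sorted(set(t) | set(i))
    nt, ni = sum(t.values()), sum(i.values())
    xs = np.arange(len(sizes))
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(xs - 0.2, [t[s] / nt for s in sizes], width=0.4, label="true")
    ax.bar(xs + 0.2, [i[s] / ni for s in sizes], width=0.4, label="inferred")
    ax.set_xticks(xs, [str(s) for s in sizes])
    ax.set_xlabel("duplication size")
    ax.set_ylabel("frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
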
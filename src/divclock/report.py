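"""Experiment orchestration: the prior x clock simulation grid and its summaries.

One experiment = a list of generating conditions (tree model, clock level,
taxon count, alignment length, replicates) crossed with an inference grid of
tree-prior x clock-mode combinations.  For every replicate the pipeline
simulates a chronogram, branch rates and an alignment; re-estimates a dated
tree under each inference combination; rescales it to the true root height;
and estimates diversification parameters (Yule lambda-hat and birth-death
r-hat) from both the original and the re-estimated chronograms.  All outputs
are plain text (Newick, FASTA, CSV) plus LTT overlay plots; everything is
reproducible bit-exactly from the root seed.

The tree-prior label of an inference combination does not change the point
estimate (the dating surrogate is prior-free), so each clock mode is
estimated once per replicate and reported under both prior labels.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clocksim, divest, seqsim, treeinfer, treesim
from .trees import from_newick, rng_from, to_newick

INFERENCE_GRID = [
    ("yule", "strict"),
    ("yule", "relaxed"),
    ("bd", "strict"),
    ("bd", "relaxed"),
]


@dataclass(frozen=True)
class Condition:
    """One generating condition of the simulation design."""

    tree_model: str  # "yule" | "bd"
    clock: str  # "strict" | "low" | "medium" | "high"
    n_taxa: int
    seq_length: int
    replicates: int = 10

    def __post_init__(self):
        if self.tree_model not in ("yule", "bd"):
            raise ValueError("tree_model must be 'yule' or 'bd'")
        if self.clock not in ("strict", "low", "medium", "high"):
            raise ValueError("clock must be strict/low/medium/high")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.tree_model}-{self.clock}-n{self.n_taxa}-L{self.seq_length}"


@dataclass
class ExperimentConfig:
    """Declarative description of a full experiment; round-trips through YAML."""

    conditions: list[Condition]
    inference: list[tuple[str, str]] = field(default_factory=lambda: list(INFERENCE_GRID))
    root_seed: int = 1
    crown_age: float = 5.0
    epsilon: float = 0.5
    n0: int = 2
    smoothing: float = 1.0
    gamma_categories: int = 4

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "conditions": [asdict(c) for c in self.conditions],
            "inference": [list(pair) for pair in self.inference],
            "root_seed": self.root_seed,
            "crown_age": self.crown_age,
            "epsilon": self.epsilon,
            "n0": self.n0,
            "smoothing": self.smoothing,
            "gamma_categories": self.gamma_categories,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            conditions=[Condition(**c) for c in doc["conditions"]],
            inference=[tuple(p) for p in doc.get("inference", INFERENCE_GRID)],
            root_seed=int(doc.get("root_seed", 1)),
            crown_age=float(doc.get("crown_age", 5.0)),
            epsilon=float(doc.get("epsilon", 0.5)),
            n0=int(doc.get("n0", 2)),
            smoothing=float(doc.get("smoothing", 1.0)),
            gamma_categories=int(doc.get("gamma_categories", 4)),
        )

    @classmethod
    def default(cls, root_seed: int = 1) -> "ExperimentConfig":
        """The core 2 tree-priors x 2 clocks grid at 25 and 100 taxa.

        UCLN generation uses the low-heterogeneity preset here; the
        medium/high presets are a separate sweep.
        """
        conds = [
            Condition(tm, ck, n, 5000, 10)
            for tm in ("yule", "bd")
            for ck in ("strict", "low")
            for n in (25, 100)
        ]
        return cls(conditions=conds, root_seed=root_seed)

    # -- model plumbing ----------------------------------------------------
    def tree_params(self, cond: Condition):
        r = treesim.expected_net_diversification(cond.n_taxa, self.n0, self.crown_age)
        if cond.tree_model == "yule":
            return treesim.YuleParams(birth_rate=r)
        return treesim.BDParams(r=r, epsilon=self.epsilon)

    def clock_params(self, cond: Condition):
        if cond.clock == "strict":
            return clocksim.StrictClockParams()
        return clocksim.UCLNClockParams.preset(cond.clock)


# ---------------------------------------------------------------------------
# LTT curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LTTCurve:
    """Lineage-through-time step function: counts start at 2 at the root."""

    times: np.ndarray  # event times since the root, ascending; length n - 1
    counts: np.ndarray  # lineage count reached at each event; 2, 3, ..., n

    def count_at(self, time_since_root) -> np.ndarray:
        """Lineage count at arbitrary times since the root (step evaluation)."""
        t = np.asarray(time_since_root, dtype=float)
        return np.searchsorted(self.times, t, side="right") + 1


def ltt_curve(tree) -> LTTCurve:
    """LTT curve of a chronogram, from its branching times."""
    bt = treesim.branching_times(tree)
    crown = bt[0]
    times = crown - bt  # ascending: 0 (root), then later events
    counts = np.arange(2, len(bt) + 2)
    return LTTCurve(times=times, counts=counts)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

_STAGE_TREE, _STAGE_CLOCK, _STAGE_SEQ = 0, 1, 2


def simulate_stage(config: ExperimentConfig, outdir: Path) -> list[str]:
    """Simulate chronograms, branch rates and alignments for every replicate."""
    outdir = Path(outdir)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    gtr = seqsim.GTRParams.nuclear_rrna()
    failures: list[str] = []
    for ci, cond in enumerate(config.conditions):
        for rep in range(cond.replicates):
            try:
                tree = treesim.simulate_chronogram(
                    config.tree_params(cond),
                    cond.n_taxa,
                    config.crown_age,
                    rng_from(config.root_seed, _STAGE_TREE, ci, rep),
                )
                rates = clocksim.draw_branch_rates(
                    tree, config.clock_params(cond), rng_from(config.root_seed, _STAGE_CLOCK, ci, rep)
                )
                phylo = clocksim.apply_rates(tree, rates)
                aln = seqsim.simulate_alignment(
                    phylo, gtr, cond.seq_length, rng_from(config.root_seed, _STAGE_SEQ, ci, rep)
                )
                stem = f"{cond.name}_rep{rep}"
                with open(outdir / "trees" / f"{stem}_true.nwk", "w") as fh:
                    fh.write(to_newick(tree) + "\n")
                rates.to_csv(outdir / "trees" / f"{stem}_rates.csv")
                aln.to_fasta(outdir / "alignments" / f"{stem}.fasta")
            except Exception:
                failures.append(f"simulate:{cond.name}:rep{rep}\n{traceback.format_exc()}")
    return failures


def infer_stage(config: ExperimentConfig, outdir: Path) -> list[str]:
    """Re-estimate a dated tree for every replicate under each clock mode."""
    outdir = Path(outdir)
    (outdir / "inferred").mkdir(parents=True, exist_ok=True)
    gtr = seqsim.GTRParams.nuclear_rrna()
    clock_modes = sorted({ck for _, ck in config.inference})
    failures: list[str] = []
    for cond in config.conditions:
        for rep in range(cond.replicates):
            stem = f"{cond.name}_rep{rep}"
            try:
                aln = seqsim.Alignment.from_fasta(outdir / "alignments" / f"{stem}.fasta")
            except FileNotFoundError:
                failures.append(f"infer:{stem}: missing alignment (run simulate first)")
                continue
            for clock_mode in clock_modes:
                try:
                    est = treeinfer.infer_chronogram(
                        aln,
                        gtr,
                        treeinfer.InferenceConfig(
                            clock_mode=clock_mode,
                            smoothing=config.smoothing,
                            gamma_categories=config.gamma_categories,
                        ),
                        root_age=config.crown_age,
                    )
                    # the prior label does not alter the estimate: write the
                    # same tree under every prior sharing this clock mode
                    for prior, ck in config.inference:
                        if ck != clock_mode:
                            continue
                        path = outdir / "inferred" / f"{stem}_{prior}_{ck}.nwk"
                        with open(path, "w") as fh:
                            fh.write(to_newick(est.chronogram) + "\n")
                    if clock_mode == "relaxed" and est.rates is not None:
                        with open(outdir / "inferred" / f"{stem}_relaxed_rates.csv", "w") as fh:
                            fh.write("branch,rate\n")
                            for bid, rate in est.rates.items():
                                fh.write(f"{bid},{rate:.10g}\n")
                except Exception:
                    failures.append(f"infer:{stem}:{clock_mode}\n{traceback.format_exc()}")
    return failures


def estimate_stage(config: ExperimentConfig, outdir: Path) -> list[str]:
    """Diversification MLEs from original and re-estimated chronograms."""
    outdir = Path(outdir)
    rows = []
    failures: list[str] = []
    for cond in config.conditions:
        true_r = treesim.expected_net_diversification(cond.n_taxa, config.n0, config.crown_age)
        for rep in range(cond.replicates):
            stem = f"{cond.name}_rep{rep}"
            sources = [("original", outdir / "trees" / f"{stem}_true.nwk")]
            for prior, ck in config.inference:
                sources.append((f"{prior}:{ck}", outdir / "inferred" / f"{stem}_{prior}_{ck}.nwk"))
            for source, path in sources:
                try:
                    tree = from_newick(path.read_text())
                    bt = treesim.branching_times(tree)
                    ye = divest.yule_mle(bt)
                    be = divest.bd_mle(bt)
                    rows.append(
                        {
                            "condition": cond.name,
                            "tree_model": cond.tree_model,
                            "clock": cond.clock,
                            "n_taxa": cond.n_taxa,
                            "seq_length": cond.seq_length,
                            "replicate": rep,
                            "source": source,
                            "true_r": true_r,
                            "lambda_hat": ye.lambda_hat,
                            "yule_loglik": ye.loglik,
                            "r_hat": be.r_hat,
                            "eps_hat": be.eps_hat,
                            "bd_loglik": be.loglik,
                            "converged": ye.converged and be.converged,
                        }
                    )
                except Exception:
                    failures.append(f"estimate:{stem}:{source}\n{traceback.format_exc()}")
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "estimates.csv", index=False, float_format="%.10g")
    return failures


def summarize(estimates: pd.DataFrame) -> pd.DataFrame:
    """Comparison table: median and quartiles of lambda-hat and r-hat.

    One row per condition x source; the ``original`` source is the reference
    distribution (estimates from the trees data were simulated on).
    """
    if estimates.empty:
        raise ValueError("no estimates to summarize")
    rows = []
    for (cond, source), grp in estimates.groupby(["condition", "source"], sort=True):
        row = {"condition": cond, "source": source, "n_replicates": len(grp)}
        for par in ("lambda_hat", "r_hat"):
            row[f"{par}_median"] = grp[par].median()
            row[f"{par}_q25"] = grp[par].quantile(0.25)
            row[f"{par}_q75"] = grp[par].quantile(0.75)
        row["true_r"] = grp["true_r"].iloc[0]
        rows.append(row)
    out = pd.DataFrame(rows)
    if not (out["source"] == "original").any():
        raise ValueError("comparison table requires the original-trees reference column")
    return out


def report_stage(config: ExperimentConfig, outdir: Path) -> list[str]:
    """Summary table and LTT overlay plots (log-count axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    failures: list[str] = []
    df = pd.read_csv(outdir / "estimates.csv")
    summarize(df).to_csv(outdir / "summary.csv", index=False, float_format="%.10g")

    (outdir / "plots").mkdir(exist_ok=True)
    for cond in config.conditions:
        for prior, ck in config.inference:
            try:
                fig, ax = plt.subplots(figsize=(5, 4))
                for rep in range(cond.replicates):
                    stem = f"{cond.name}_rep{rep}"
                    true = from_newick((outdir / "trees" / f"{stem}_true.nwk").read_text())
                    lt = ltt_curve(true)
                    ax.step(
                        np.append(lt.times, config.crown_age),
                        np.log(np.append(lt.counts, lt.counts[-1])),
                        where="post", color="0.7", lw=2.0,
                        label="original" if rep == 0 else None,
                    )
                    est_path = outdir / "inferred" / f"{stem}_{prior}_{ck}.nwk"
                    if est_path.exists():
                        le = ltt_curve(from_newick(est_path.read_text()))
                        ax.step(
                            np.append(le.times, config.crown_age),
                            np.log(np.append(le.counts, le.counts[-1])),
                            where="post", color="k", lw=0.8,
                            label="estimated" if rep == 0 else None,
                        )
                ax.set_xlabel("time since root")
                ax.set_ylabel("ln(lineages)")
                ax.set_title(f"{cond.name} | {prior}:{ck}")
                ax.legend(frameon=False, fontsize=8)
                fig.tight_layout()
                fig.savefig(outdir / "plots" / f"ltt_{cond.name}_{prior}_{ck}.png", dpi=120)
                plt.close(fig)
            except Exception:
                failures.append(f"report:{cond.name}:{prior}:{ck}\n{traceback.format_exc()}")
    return failures


def run_experiment(config: ExperimentConfig, outdir) -> dict:
    """Run all stages; returns a manifest with per-stage failure lists."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest = {"failures": {}}
    for name, stage in [
        ("simulate", simulate_stage),
        ("infer", infer_stage),
        ("estimate", estimate_stage),
        ("report", report_stage),
    ]:
        fails = stage(config, outdir)
        manifest["failures"][name] = fails
    manifest["n_failures"] = sum(len(v) for v in manifest["failures"].values())
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
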
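"""Desk-scale orchestration of divergence and fragmentation sweeps.

A sweep generates, for each value on its axis (generations-per-unit-time or
mean fragment length) and each replicate, a random tree, a simulated family,
and one predicted MSA per tool; predictions are scored against the simulator's
reference MSA (SPS, CS, CSL) and aggregated with mean and Student-t 95%
confidence intervals.  Replicate ``r`` reuses seed ``base_seed + r`` across
axis values and tools, so scores are paired for the rank tests.

Built-in tools: ``refiner`` (this package's iterative transitive aligner) and
``identity`` (emits the reference MSA — a harness-level sanity oracle that
must score SPS=CS=1, CSL=0 everywhere).  External aligners are described by
an :class:`ExternalAligner` adapter (command template, FASTA in / aligned
FASTA out) and are skipped with a warning when their binary is absent.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import refiner as _refiner
from .fixtures import FixtureSpec, make_rate_matrix, make_seed_sequence
from .formats_io import Msa, SeqRecord, TripletRateMatrix, read_msa_fasta, write_fasta
from .msa_metrics import metric_report
from .te_forward_evolve import (
    EvolutionResult,
    FragmentationModel,
    SimConfig,
    simulate,
)
from .tree_sim import TreeConfig, generate_dna_transposon_tree, generate_master_gene_tree

__all__ = [
    "SweepSpec",
    "BenchResult",
    "ExternalAligner",
    "run_sweep",
    "compare_tools",
    "fragment_table",
]


@dataclass
class ExternalAligner:
    """Adapter for a shell MSA tool: FASTA in, aligned FASTA out.

    ``command`` is a template with ``{infile}`` and ``{outfile}`` holes, e.g.
    ``"mafft --localpair --maxiterate 1000 {infile} > {outfile}"``.
    """

    name: str
    command: str

    def available(self) -> bool:
        return shutil.which(self.command.split()[0]) is not None

    def run(self, records: list[SeqRecord]) -> Msa:
        with tempfile.TemporaryDirectory() as tmp:
            infile = Path(tmp) / "input.fa"
            outfile = Path(tmp) / "output.fa"
            write_fasta(records, infile)
            cmd = self.command.format(infile=infile, outfile=outfile)
            subprocess.run(cmd, shell=True, check=True, capture_output=True)
            return read_msa_fasta(outfile, drop_all_gap_columns=True)


@dataclass
class SweepSpec:
    """One benchmark sweep along ``axis`` in {"gput", "fragment_mean"}."""

    axis: str = "gput"
    values: list = field(default_factory=lambda: [100, 1000, 3000])
    replicates: int = 10
    n_sequences: int = 100
    tools: list = field(default_factory=lambda: ["refiner", "identity"])
    tree_model: str = "transposon"  # or "mastergene"
    gput: int = 100  # base value; overridden per-point on the gput axis
    fragmentation: FragmentationModel | None = None  # base; overridden on frag axis
    seed_length: int = 1200
    base_seed: int = 0
    external: dict[str, ExternalAligner] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis not in ("gput", "fragment_mean"):
            raise ValueError("axis must be 'gput' or 'fragment_mean'")
        if not self.values:
            raise ValueError("values must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class BenchResult:
    scores: pd.DataFrame  # tool, value, replicate, sps, cs, csl, divergence
    skipped: list[str]
    spec: SweepSpec

    def aggregate(self) -> pd.DataFrame:
        """Mean and Student-t 95% CI of each metric per (tool, value)."""
        rows = []
        for (tool, value), grp in self.scores.groupby(["tool", "value"]):
            entry = {"tool": tool, "value": value, "n": len(grp)}
            for metric in ("sps", "cs", "csl", "divergence"):
                vals = grp[metric].to_numpy(dtype=float)
                mean = float(np.mean(vals))
                entry[f"{metric}_mean"] = mean
                if len(vals) > 1 and np.std(vals, ddof=1) > 0:
                    lo, hi = stats.t.interval(
                        0.95, len(vals) - 1, loc=mean, scale=stats.sem(vals)
                    )
                else:
                    lo = hi = mean
                entry[f"{metric}_ci_lo"] = float(lo)
                entry[f"{metric}_ci_hi"] = float(hi)
            rows.append(entry)
        return pd.DataFrame(rows)


def _predict(tool, records: list[SeqRecord], reference: Msa) -> Msa:
    if tool == "identity":
        return reference
    if tool == "refiner":
        return _refiner.refine(records).msa
    if isinstance(tool, ExternalAligner):
        return tool.run(records)
    raise ValueError(f"unknown tool {tool!r}")


def _simulate_point(
    spec: SweepSpec, value, replicate: int, seed_record: SeqRecord, rates: TripletRateMatrix
) -> EvolutionResult:
    run_seed = int(spec.base_seed + replicate) % (2**31)
    tree_cfg = TreeConfig(n_leaves=spec.n_sequences, rng_seed=run_seed)
    if spec.tree_model == "transposon":
        tree = generate_dna_transposon_tree(tree_cfg)
    elif spec.tree_model == "mastergene":
        tree = generate_master_gene_tree(tree_cfg)
    else:
        raise ValueError(f"unknown tree model {spec.tree_model!r}")
    gput = int(value) if spec.axis == "gput" else spec.gput
    if spec.axis == "fragment_mean":
        base = spec.fragmentation or FragmentationModel(mean_length=float(value))
        frag = FragmentationModel(
            mean_length=float(value),
            sd_length=base.sd_length,
            min_fragment=base.min_fragment,
            min_full_length=base.min_full_length,
        )
    else:
        frag = spec.fragmentation
    config = SimConfig(gput=gput, rng_seed=run_seed, fragmentation=frag)
    return simulate(tree, seed_record, rates, config)


def run_sweep(spec: SweepSpec) -> BenchResult:
    """Run the full sweep; returns per-run scores in long format."""
    seed_record = make_seed_sequence(
        FixtureSpec(seed_length=spec.seed_length, cpg_enrichment=3.0, rng_seed=spec.base_seed)
    )
    rates = make_rate_matrix()
    skipped: list[str] = []
    tools = []
    for tool in spec.tools:
        if isinstance(tool, str) and tool in spec.external:
            tool = spec.external[tool]
        if isinstance(tool, ExternalAligner) and not tool.available():
            warnings.warn(f"external tool {tool.name!r} not found; skipping")
            skipped.append(tool.name)
            continue
        tools.append(tool)

    rows = []
    for value in spec.values:
        for r in range(spec.replicates):
            result = _simulate_point(spec, value, r, seed_record, rates)
            reference = result.reference_msa
            ref_consensus = _refiner.call_consensus(reference)
            for tool in tools:
                name = tool.name if isinstance(tool, ExternalAligner) else tool
                predicted = _predict(tool, result.extant, reference)
                pred_consensus = _refiner.call_consensus(predicted)
                report = metric_report(predicted, reference, pred_consensus, ref_consensus)
                rows.append(
                    {
                        "tool": name,
                        "value": value,
                        "replicate": r,
                        "sps": report.sps,
                        "cs": report.cs,
                        "csl": report.csl,
                        "divergence": result.mean_divergence(),
                    }
                )
    return BenchResult(scores=pd.DataFrame(rows), skipped=skipped, spec=spec)


def compare_tools(
    result: BenchResult, metric: str = "sps", alternative: str = "two-sided"
) -> dict:
    """Kruskal–Wallis across tools and pairwise Wilcoxon signed-rank tests.

    Replicates are paired by their shared seed.  When a pair of tools has
    identical score vectors the signed-rank test is undefined; its p-value is
    reported as ``nan`` with a note.  A Bonferroni-corrected copy of the
    pairwise p-values is included; no further multiplicity claim is made.
    """
    df = result.scores
    tools = sorted(df["tool"].unique())
    if len(tools) < 2:
        raise ValueError("need at least 2 tools to compare")
    report: dict = {"metric": metric, "kruskal": {}, "wilcoxon": {}, "notes": []}
    for value, grp in df.groupby("value"):
        samples = []
        for tool in tools:
            sub = grp[grp["tool"] == tool].sort_values("replicate")
            if len(sub) != result.spec.replicates:
                raise ValueError(f"unpaired data for tool {tool!r} at value {value!r}")
            samples.append(sub[metric].to_numpy(dtype=float))
        if all(np.array_equal(samples[0], s) for s in samples[1:]) and np.ptp(
            np.concatenate(samples)
        ) == 0:
            report["kruskal"][value] = 1.0
            report["notes"].append(f"value {value}: all scores identical; H test trivial")
        else:
            _, p = stats.kruskal(*samples)
            report["kruskal"][value] = float(p)
        for i in range(len(tools)):
            for j in range(i + 1, len(tools)):
                diffs = samples[i] - samples[j]
                key = (tools[i], tools[j], value)
                if np.all(diffs == 0):
                    report["wilcoxon"][key] = float("nan")
                    report["notes"].append(
                        f"{key}: identical paired scores; signed-rank test undefined"
                    )
                else:
                    _, p = stats.wilcoxon(
                        samples[i], samples[j], alternative=alternative, method="exact"
                    )
                    report["wilcoxon"][key] = float(p)
    n_tests = max(len(report["wilcoxon"]), 1)
    report["wilcoxon_bonferroni"] = {
        k: min(1.0, v * n_tests) if np.isfinite(v) else v
        for k, v in report["wilcoxon"].items()
    }
    return report


def fragment_table(result: EvolutionResult, window: int = 10) -> pd.DataFrame:
    """Per-fragment extent and windowed divergence over the reference MSA.

    For each row: the first/last occupied column (half-open extent) and, per
    ``window``-column window inside the extent, the fraction of residues
    disagreeing with the column-majority base.  Supports fragmentation
    heatmap visualisations.
    """
    msa = result.reference_msa
    chars = np.array([list(row) for _, row in msa.rows])
    majority = []
    for c in range(msa.ncols):
        col = chars[:, c]
        bases, counts = np.unique(col[col != "-"], return_counts=True)
        majority.append(bases[np.argmax(counts)] if len(bases) else "-")
    majority = np.array(majority)
    rows = []
    for i, (rid, _) in enumerate(msa.rows):
        occupied = np.flatnonzero(chars[i] != "-")
        start, end = int(occupied[0]), int(occupied[-1]) + 1
        for w in range(start, end, window):
            w_end = min(w + window, end)
            seg = chars[i, w:w_end]
            maj = majority[w:w_end]
            mask = seg != "-"
            div = float(np.mean(seg[mask] != maj[mask])) if mask.any() else float("nan")
            rows.append(
                {
                    "id": rid,
                    "start": start,
                    "end": end,
                    "window_start": w,
                    "window_end": w_end,
                    "divergence": div,
                }
            )
    return pd.DataFrame(rows)
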
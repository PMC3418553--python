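"""End-to-end orchestration and the run report.

The stages run in screening order: preprocessing of both
matrices, dual-gate differential calling, sign-constrained
anti-correlation screening with family-wide BH retention, dual-source
target-prediction intersection, pathway enrichment over the measured
universe, and (optionally) qPCR validation. Every stage writes its TSV
artifact; the run report collects headline counts and is emitted both as
text and JSON.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import anticorr, differential, enrichment, preprocess, qpcr, synthetic, targets
from .matrix import read_matrix, write_matrix
from .preprocess import MIRNA_FLAGS, MRNA_FLAGS, FlagPolicy
from .synthetic import SimConfig

log = logging.getLogger("mirpair")

__all__ = ["PipelineConfig", "RunReport", "run_all", "run_benchmark", "simulate_inputs"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and switches for a full run.

    Shipped defaults: dual DE gate at BH FDR < 0.05 and SAM q < 0.05;
    correlation screen r < -0.5 with p < 0.05 and pair-family BH
    FDR < 0.3; enrichment cut at FDR < 0.05; qPCR CT ceiling 35 cycles.
    """

    outdir: str = "mirpair_out"
    # inputs
    mirna_matrix: str | None = None
    mirna_flags: str | None = None
    mrna_matrix: str | None = None
    mrna_flags: str | None = None
    metadata: str | None = None
    table_a: str | None = None
    table_b: str | None = None
    gmt: str | None = None
    qpcr_mirna: str | None = None
    qpcr_mrna: str | None = None
    qpcr_pairs: list = field(default_factory=list)  # [[mirna_assay, mrna_assay], ...]
    # thresholds
    flag_min_fraction: float = 0.75
    de_fdr_max: float = 0.05
    de_q_max: float = 0.05
    corr_r_max: float = -0.5
    corr_p_max: float = 0.05
    corr_fdr_max: float = 0.3
    enrich_fdr_max: float = 0.05
    ct_max: float = 35.0
    # switches
    enforce_direction: bool = True
    ease: bool = True
    paired_t: bool = True
    seed: int = 0

    def validate(self):
        if not (0 < self.de_fdr_max <= 1 and 0 < self.de_q_max <= 1):
            raise ValueError("DE thresholds must lie in (0, 1]")
        if self.corr_r_max >= 0:
            raise ValueError("corr_r_max must be negative (anti-correlation)")
        if not (0 <= self.corr_fdr_max <= 1):
            raise ValueError("corr_fdr_max must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunReport:
    config: dict
    seed: int
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def check_arithmetic(self) -> None:
        """Arm counts must partition the final pairs."""
        c = self.counts
        if "final_pairs" in c:
            total = c["up_mirna_down_mrna"] + c["down_mirna_up_mrna"]
            if total != c["final_pairs"]:
                raise AssertionError("final pair arm counts do not sum to the total")

    def to_text(self) -> str:
        lines = ["mirpair run report", "=" * 40, f"seed: {self.seed}", "", "counts:"]
        for k, v in self.counts.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
        lines.append("stage timings (s):")
        for k, v in self.timings.items():
            lines.append(f"  {k}: {v:.2f}")
        lines.append("")
        lines.append("config:")
        for k, v in self.config.items():
            lines.append(f"  {k}: {v}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "counts": self.counts, "timings": self.timings, "config": self.config},
            indent=2,
            default=str,
        )


# ---------------------------------------------------------------------

def simulate_inputs(sim: SimConfig, outdir) -> dict:
    """Write a complete synthetic input tree; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mirna_m, mrna_m, truth = synthetic.generate_cohort(sim)
    mirna_seqs, utr_seqs = synthetic.generate_sequences(truth, sim)
    tab_a, tab_b = synthetic.generate_prediction_tables(truth, sim)
    gene_sets = synthetic.generate_gene_sets(truth, sim)

    paths = {
        "mirna_matrix": str(out / "mirna_matrix.tsv"),
        "mirna_flags": str(out / "mirna_flags.tsv"),
        "mrna_matrix": str(out / "mrna_matrix.tsv"),
        "mrna_flags": str(out / "mrna_flags.tsv"),
        "metadata": str(out / "samples.tsv"),
        "mirna_fasta": str(out / "mirna.fa"),
        "utr_fasta": str(out / "utr.fa"),
        "table_a": str(out / "predictions_A.tsv"),
        "table_b": str(out / "predictions_B.tsv"),
        "gmt": str(out / "gene_sets.gmt"),
        "truth_edges": str(out / "truth_edges.tsv"),
    }
    write_matrix(mirna_m, paths["mirna_matrix"], paths["metadata"], paths["mirna_flags"])
    write_matrix(mrna_m, paths["mrna_matrix"], flags_path=paths["mrna_flags"])
    synthetic.write_fasta(mirna_seqs, paths["mirna_fasta"])
    synthetic.write_fasta(utr_seqs, paths["utr_fasta"])
    targets.write_prediction_table(tab_a, paths["table_a"])
    targets.write_prediction_table(tab_b, paths["table_b"])
    enrichment.write_gmt(gene_sets, paths["gmt"])
    with open(paths["truth_edges"], "w") as fh:
        fh.write("mirna_id\tmrna_id\n")
        for mi, mr in sorted(truth.edges):
            fh.write(f"{mi}\t{mr}\n")

    # qPCR plates for a handful of planted edges plus one failing assay
    edge_list = sorted(truth.edges)[:4]
    if edge_list:
        mirna_assays = sorted({mi for mi, _ in edge_list})
        mrna_assays = sorted({mr for _, mr in edge_list})
        failing = (mirna_assays[0],)
        plate_mi = synthetic.generate_qpcr_plate(truth, sim, mirna_assays, failing_assays=failing)
        plate_mr = synthetic.generate_qpcr_plate(truth, sim, mrna_assays)
        paths["qpcr_mirna"] = str(out / "qpcr_mirna.csv")
        paths["qpcr_mrna"] = str(out / "qpcr_mrna.csv")
        synthetic.write_qpcr_table(plate_mi, paths["qpcr_mirna"])
        synthetic.write_qpcr_table(plate_mr, paths["qpcr_mrna"])
        paths["qpcr_pairs"] = [[mi, mr] for mi, mr in edge_list]
    return paths


def _stage(report, name):
    class _Timer:
        def __enter__(self):
            log.info("=== stage: %s ===", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            report.timings[name] = time.perf_counter() - self.t0

    return _Timer()


def run_all(config: PipelineConfig) -> RunReport:
    """Run every stage from files to files; artifacts land in ``outdir``."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config), seed=config.seed)

    with _stage(report, "preprocess"):
        mirna_m = read_matrix(config.mirna_matrix, config.metadata, config.mirna_flags)
        mrna_m = read_matrix(config.mrna_matrix, config.metadata, config.mrna_flags)
        mirna_m = preprocess.filter_flags(
            mirna_m, FlagPolicy(MIRNA_FLAGS, config.flag_min_fraction)
        ) if mirna_m.flags is not None else mirna_m
        mrna_m = preprocess.filter_flags(
            mrna_m, FlagPolicy(MRNA_FLAGS, config.flag_min_fraction)
        ) if mrna_m.flags is not None else mrna_m
        mirna_m = preprocess.quantile_normalize(mirna_m)
        mrna_m = preprocess.quantile_normalize(mrna_m)
        report.counts["mirna_features"] = mirna_m.n_features
        report.counts["mrna_features"] = mrna_m.n_features

    with _stage(report, "differential"):
        params = differential.SamParams(seed=config.seed)
        de_mi = differential.call_differential(
            mirna_m, config.de_fdr_max, config.de_q_max, params, paired=config.paired_t
        )
        de_mr = differential.call_differential(
            mrna_m, config.de_fdr_max, config.de_q_max, params, paired=config.paired_t
        )
        differential.write_differential(de_mi, out / "de_mirna.tsv")
        differential.write_differential(de_mr, out / "de_mrna.tsv")
        for label, de in (("mirna", de_mi), ("mrna", de_mr)):
            report.counts[f"de_{label}_up"] = int((de["direction"] == "up").sum())
            report.counts[f"de_{label}_down"] = int((de["direction"] == "down").sum())
            report.counts[f"de_{label}_total"] = (
                report.counts[f"de_{label}_up"] + report.counts[f"de_{label}_down"]
            )

    with _stage(report, "anticorrelation"):
        pairs = anticorr.screen_pairs(
            de_mi, de_mr, mirna_m, mrna_m,
            r_max=config.corr_r_max, p_max=config.corr_p_max,
            enforce_direction=config.enforce_direction,
        )
        pairs = anticorr.fdr_retain(pairs, config.corr_fdr_max)
        anticorr.write_pairs(pairs, out / "correlation_pairs.tsv")
        retained = pairs[pairs["retained"]] if len(pairs) else pairs
        report.counts["evaluated_pairs"] = int(len(pairs))
        report.counts["retained_pairs"] = int(len(retained))

    with _stage(report, "target_prediction"):
        src_a = targets.load_prediction_table(config.table_a, "source_A")
        src_b = targets.load_prediction_table(config.table_b, "source_B")
        both = targets.intersect_sources(src_a, src_b)
        final, summary = targets.identify_regulatory_pairs(retained, both)
        final = final.copy()
        final["sources"] = f"{src_a.name},{src_b.name}"
        final.to_csv(out / "final_pairs.tsv", sep="\t", index=False)
        report.counts["predicted_by_both"] = len(both)
        report.counts["final_pairs"] = summary["n_pairs"]
        report.counts["final_mirnas"] = summary["n_mirnas"]
        report.counts["final_mrnas"] = summary["n_mrnas"]
        report.counts["up_mirna_down_mrna"] = summary["up_mirna_down_mrna"]
        report.counts["down_mirna_up_mrna"] = summary["down_mirna_up_mrna"]

    if config.gmt:
        with _stage(report, "enrichment"):
            gene_sets = enrichment.read_gmt(config.gmt)
            universe = mrna_m.feature_ids
            study = sorted(set(final["mrna_id"])) if len(final) else []
            if study:
                regulators = {}
                for _, row in final.iterrows():
                    regulators.setdefault(row["mrna_id"], set()).add(row["mirna_id"])
                res = enrichment.enrich(study, gene_sets, universe, ease=config.ease, regulators=regulators)
            else:
                res = enrichment.enrich(["__none__"], [], ["__none__"])
            enrichment.write_enrichment(res, out / "enrichment.tsv")
            report.counts["enriched_terms"] = int(
                (res["fdr_percent"] < config.enrich_fdr_max * 100).sum()
            ) if len(res) else 0

    if config.qpcr_mirna and config.qpcr_mrna:
        with _stage(report, "qpcr"):
            plate_mi = qpcr.analyze_plate(qpcr.read_ct_table(config.qpcr_mirna), ct_max=config.ct_max)
            plate_mr = qpcr.analyze_plate(qpcr.read_ct_table(config.qpcr_mrna), ct_max=config.ct_max)
            plate_mi.measurements.to_csv(out / "qpcr_mirna_neg_ddct.tsv", sep="\t", index=False)
            plate_mr.measurements.to_csv(out / "qpcr_mrna_neg_ddct.tsv", sep="\t", index=False)
            qc_rows = [vars(q) for q in (*plate_mi.qc.values(), *plate_mr.qc.values())]
            pd.DataFrame(qc_rows).to_csv(out / "qpcr_assay_qc.tsv", sep="\t", index=False)
            tests = []
            for plate in (plate_mi, plate_mr):
                for assay, q in plate.qc.items():
                    if q.excluded:
                        continue
                    t, p = qpcr.paired_group_test(plate.assay(assay))
                    tests.append({"assay_id": assay, "t_stat": t, "p_value": p})
            pd.DataFrame(tests).to_csv(out / "qpcr_paired_tests.tsv", sep="\t", index=False)
            if config.qpcr_pairs:
                val = qpcr.validate_pairs(plate_mi, plate_mr, [tuple(p) for p in config.qpcr_pairs])
                val.to_csv(out / "qpcr_pair_validation.tsv", sep="\t", index=False)
                report.counts["qpcr_pairs_significant"] = int(val["significant"].sum())
                report.counts["qpcr_pairs_evaluable"] = int(val["evaluable"].sum())
            report.counts["qpcr_assays_excluded"] = sum(
                q.excluded for plate in (plate_mi, plate_mr) for q in plate.qc.values()
            )

    report.check_arithmetic()
    (out / "report.txt").write_text(report.to_text())
    (out / "report.json").write_text(report.to_json())
    log.info("run complete: %s", report.counts)
    return report


# ---------------------------------------------------------------------
# in-memory benchmark (no file I/O), used by tests and the acceptance run

@dataclass
class BenchmarkResult:
    final: pd.DataFrame
    truth: object
    report_counts: dict
    recall: float
    precision: float


def run_benchmark(sim: SimConfig, config: PipelineConfig | None = None) -> BenchmarkResult:
    """Simulate a cohort and run the core screen in memory.

    Recall/precision compare the final pair list against the planted
    edges of the truth network.
    """
    config = config or PipelineConfig(seed=sim.seed)
    mirna_m, mrna_m, truth = synthetic.generate_cohort(sim)
    tab_a, tab_b = synthetic.generate_prediction_tables(truth, sim)
    mirna_m = preprocess.quantile_normalize(mirna_m)
    mrna_m = preprocess.quantile_normalize(mrna_m)
    params = differential.SamParams(seed=config.seed)
    de_mi = differential.call_differential(mirna_m, config.de_fdr_max, config.de_q_max, params)
    de_mr = differential.call_differential(mrna_m, config.de_fdr_max, config.de_q_max, params)
    pairs = anticorr.screen_pairs(
        de_mi, de_mr, mirna_m, mrna_m,
        r_max=config.corr_r_max, p_max=config.corr_p_max,
        enforce_direction=config.enforce_direction,
    )
    pairs = anticorr.fdr_retain(pairs, config.corr_fdr_max)
    retained = pairs[pairs["retained"]] if len(pairs) else pairs
    both = targets.intersect_sources(tab_a, tab_b)
    final, summary = targets.identify_regulatory_pairs(retained, both)
    found = {(r["mirna_id"], r["mrna_id"]) for _, r in final.iterrows()}
    tp = len(found & truth.edges)
    recall = tp / len(truth.edges) if truth.edges else float("nan")
    precision = tp / len(found) if found else (1.0 if not truth.edges else 0.0)
    counts = {
        "de_mirna_total": int((de_mi["direction"] != "null").sum()),
        "de_mrna_total": int((de_mr["direction"] != "null").sum()),
        "evaluated_pairs": int(len(pairs)),
        "retained_pairs": int(len(retained)),
        **summary,
    }
    return BenchmarkResult(final=final, truth=truth, report_counts=counts,
                           recall=recall, precision=precision)
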
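"""Synthetic paired tumor/normal cohorts with a planted repression network.

The generator emulates the study design the pipeline targets: a small
matched tumor/normal cohort profiled on both a miRNA and an mRNA array,
a subset of miRNAs shifted up or down in tumor, and a planted set of
repressive miRNA -> mRNA edges that make each target track the negative
of its regulator across samples (linear-Gaussian coupling on the log2
scale). Matching mature sequences, imperfect two-source prediction
tables, gene sets and qPCR CT plates are generated from the same truth
so every downstream stage is testable without downloads.

All randomness flows through ``SimConfig.seed``; each generator derives
an independent, deterministic stream from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .preprocess import MIRNA_FLAGS, MRNA_FLAGS
from .targets import PredictionSource, seed_patterns

__all__ = [
    "SimConfig",
    "TruthNetwork",
    "generate_cohort",
    "generate_sequences",
    "generate_prediction_tables",
    "generate_gene_sets",
    "generate_qpcr_plate",
    "write_fasta",
    "write_qpcr_table",
]

_BASES_RNA = "ACGU"
_BASES_DNA = "ACGT"

# stream keys so each generator gets an independent deterministic RNG
_STREAM_COHORT, _STREAM_SEQ, _STREAM_PRED_A, _STREAM_PRED_B, _STREAM_QPCR, _STREAM_GMT = range(6)


@dataclass(kw_only=True)
class SimConfig:
    """Study-design parameters of the simulated cohort."""

    seed: int
    n_pairs: int = 8
    n_mirna: int = 200
    n_mrna: int = 2000
    n_de_mirna_up: int = 16
    n_de_mirna_down: int = 16
    n_true_edges: int = 30
    de_effect: float = 2.0
    coupling: float = 0.9
    noise_sd: float = 0.3
    patient_sd: float = 0.0
    pred_fnr: float = 0.1
    pred_fpr: float = 0.05
    mirna_len: int = 22
    utr_len: int = 150
    n_qpcr_pairs: int = 40

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_pairs", "n_mirna", "n_mrna", "mirna_len", "utr_len", "n_qpcr_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_de_mirna_up", "n_de_mirna_down", "n_true_edges"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_de_mirna_up + self.n_de_mirna_down > self.n_mirna:
            raise ValueError("more planted DE miRNAs than miRNAs")
        n_de = self.n_de_mirna_up + self.n_de_mirna_down
        if self.n_true_edges > 0 and n_de == 0:
            raise ValueError("edges require at least one planted DE miRNA")
        if self.n_true_edges > self.n_mrna:
            raise ValueError("more planted edges than mRNAs (targets are distinct)")
        if self.n_true_edges > max(n_de, 1) * self.n_mrna:
            raise ValueError("edge count infeasible")
        for name in ("pred_fnr", "pred_fpr", "coupling"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class TruthNetwork:
    """Planted repressive edges and the planted differential directions."""

    edges: set                       # {(mirna_id, mrna_id)}
    de_direction: dict               # feature_id -> 'up' | 'down' | 'null'
    regulator_of: dict = field(default_factory=dict)  # mrna_id -> mirna_id

    def direction(self, feature_id: str) -> str:
        return self.de_direction.get(feature_id, "null")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _mirna_ids(config: SimConfig) -> list:
    return [f"mir-{i:04d}" for i in range(config.n_mirna)]


def _mrna_ids(config: SimConfig) -> list:
    return [f"gene-{i:05d}" for i in range(config.n_mrna)]


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> TruthNetwork:
    """Assign planted DE miRNAs and distinct-target repressive edges."""
    mirnas = _mirna_ids(config)
    mrnas = _mrna_ids(config)
    de_idx = rng.choice(config.n_mirna, size=config.n_de_mirna_up + config.n_de_mirna_down, replace=False)
    up_idx = de_idx[: config.n_de_mirna_up]
    down_idx = de_idx[config.n_de_mirna_up:]
    de_direction = {mirnas[i]: "up" for i in up_idx}
    de_direction.update({mirnas[i]: "down" for i in down_idx})
    edges, regulator_of = set(), {}
    if config.n_true_edges:
        target_idx = rng.choice(config.n_mrna, size=config.n_true_edges, replace=False)
        regs = rng.choice(de_idx, size=config.n_true_edges, replace=True)
        for t, r in zip(target_idx, regs):
            mi, mr = mirnas[r], mrnas[t]
            edges.add((mi, mr))
            regulator_of[mr] = mi
            de_direction[mr] = "down" if de_direction[mi] == "up" else "up"
    return TruthNetwork(edges=edges, de_direction=de_direction, regulator_of=regulator_of)


def _simulate_expression(truth: TruthNetwork, config: SimConfig, rng: np.random.Generator):
    """Expression grids (miRNA, mRNA, metadata) conditioned on a truth network.

    Per feature g and sample s the baseline is Normal(mu_g, noise_sd);
    planted DE features gain +/-de_effect in tumor samples; each
    true-edge target additionally receives ``-coupling * (regulator value
    centered across samples)``.
    """
    mirnas = _mirna_ids(config)
    mrnas = _mrna_ids(config)
    n_s = 2 * config.n_pairs
    patients = [f"P{p:02d}" for p in range(config.n_pairs)]
    samples = [f"{p}{suffix}" for p in patients for suffix in ("T", "N")]
    group = ["tumor", "normal"] * config.n_pairs
    tumor_mask = np.array([g == "tumor" for g in group])
    metadata = pd.DataFrame(
        {"patient_id": np.repeat(patients, 2), "group": group}, index=pd.Index(samples, name="sample_id")
    )

    def _baseline(n_feat):
        mu = rng.uniform(6.0, 12.0, size=n_feat)
        vals = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(n_feat, n_s))
        if config.patient_sd > 0:
            # shared intercept for the two samples of each patient
            icpt = rng.normal(0.0, config.patient_sd, size=(n_feat, config.n_pairs))
            vals += np.repeat(icpt, 2, axis=1)
        return vals

    X = _baseline(config.n_mirna)
    for i, mi in enumerate(mirnas):
        d = truth.de_direction.get(mi, "null")
        if d == "up":
            X[i, tumor_mask] += config.de_effect
        elif d == "down":
            X[i, tumor_mask] -= config.de_effect

    Y = _baseline(config.n_mrna)
    mirna_row = {mi: i for i, mi in enumerate(mirnas)}
    for t, mr in enumerate(mrnas):
        reg = truth.regulator_of.get(mr)
        if reg is not None:
            r = mirna_row[reg]
            Y[t] += -config.coupling * (X[r] - X[r].mean())

    Xdf = pd.DataFrame(X, index=pd.Index(mirnas, name="feature_id"), columns=samples)
    Ydf = pd.DataFrame(Y, index=pd.Index(mrnas, name="feature_id"), columns=samples)
    return Xdf, Ydf, metadata


def generate_cohort(config: SimConfig):
    """Simulate (miRNA matrix, mRNA matrix, truth network)."""
    rng = _rng(config, _STREAM_COHORT)
    truth = _draw_truth(config, rng)
    Xdf, Ydf, metadata = _simulate_expression(truth, config, rng)

    def _matrix(values, flag_labels):
        flags = pd.DataFrame(";".join(sorted(flag_labels)), index=values.index, columns=values.columns)
        return ExpressionMatrix(values=values, metadata=metadata.copy(), flags=flags)

    return _matrix(Xdf, MIRNA_FLAGS), _matrix(Ydf, MRNA_FLAGS), truth


# ---------------------------------------------------------------------
# sequences

def _random_seq(rng, length, alphabet):
    return "".join(alphabet[i] for i in rng.integers(0, 4, size=length))


def generate_sequences(truth: TruthNetwork, config: SimConfig, max_reject: int = 200):
    """Mature miRNA sequences and 3'UTRs consistent with the truth network.

    Every true-edge target UTR carries at least one planted 8mer site for
    its regulator; decoy UTRs are rejection-sampled until they contain no
    seed-match core for any planted DE miRNA.
    """
    rng = _rng(config, _STREAM_SEQ)
    mirna_seqs = {mi: _random_seq(rng, config.mirna_len, _BASES_RNA) for mi in _mirna_ids(config)}
    de_mirnas = [f for f, d in truth.de_direction.items() if d != "null" and f.startswith("mir-")]
    cores = {seed_patterns(mirna_seqs[mi])["6mer"] for mi in de_mirnas}

    def has_core(seq: str) -> bool:
        return any(seq[i : i + 6] in cores for i in range(len(seq) - 5))

    utr_seqs = {}
    for mr in _mrna_ids(config):
        for attempt in range(max_reject):
            seq = _random_seq(rng, config.utr_len, _BASES_DNA)
            if not has_core(seq):
                break
        else:
            raise RuntimeError(f"rejection sampling cap hit for {mr}")
        reg = truth.regulator_of.get(mr)
        if reg is not None:
            site = seed_patterns(mirna_seqs[reg])["8mer"]
            pos = int(rng.integers(0, config.utr_len - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
        utr_seqs[mr] = seq
    return mirna_seqs, utr_seqs


def write_fasta(seqs: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------
# prediction tables

def _one_prediction_source(truth, config, rng, name) -> PredictionSource:
    mirnas = _mirna_ids(config)
    mrnas = _mrna_ids(config)
    pairs = {e for e in truth.edges if rng.random() >= config.pred_fnr}
    space = config.n_mirna * config.n_mrna
    n_false = rng.binomial(space, config.pred_fpr)
    if n_false:
        flat = rng.choice(space, size=n_false, replace=False)
        for k in flat:
            pair = (mirnas[k // config.n_mrna], mrnas[k % config.n_mrna])
            if pair not in truth.edges:
                pairs.add(pair)
    return PredictionSource(name=name, pairs=pairs, provenance="external_table")


def generate_prediction_tables(truth: TruthNetwork, config: SimConfig):
    """Two imperfect, independently-drawn prediction sources.

    Each source drops true edges with probability ``pred_fnr`` and adds
    random non-edge pairs at per-pair rate ``pred_fpr``.
    """
    a = _one_prediction_source(truth, config, _rng(config, _STREAM_PRED_A), "source_A")
    b = _one_prediction_source(truth, config, _rng(config, _STREAM_PRED_B), "source_B")
    return a, b


# ---------------------------------------------------------------------
# gene sets

def generate_gene_sets(truth: TruthNetwork, config: SimConfig, n_sets: int = 20, set_size: int = 15):
    """GMT-style collection with one term enriched in true-edge targets."""
    rng = _rng(config, _STREAM_GMT)
    mrnas = _mrna_ids(config)
    targets = sorted(truth.regulator_of)
    planted = list(targets[: min(len(targets), set_size)])
    need = set_size - len(planted)
    if need > 0:
        pool = [g for g in mrnas if g not in set(planted)]
        planted += list(rng.choice(pool, size=need, replace=False))
    sets = [("set-0000", "planted pathway", sorted(planted))]
    for k in range(1, n_sets):
        members = rng.choice(len(mrnas), size=set_size, replace=False)
        sets.append((f"set-{k:04d}", f"random set {k}", sorted(mrnas[i] for i in members)))
    return sets


# ---------------------------------------------------------------------
# qPCR plates

#: documented CT mapping: assay CT = CT_A - CT_B * log2(expression)
CT_INTERCEPT = 30.0
CT_SLOPE = 1.0
REF_CT_MEAN = 20.0
REF_CT_SD = 0.25


def generate_qpcr_plate(
    truth: TruthNetwork,
    config: SimConfig,
    assays,
    n_patients: int | None = None,
    failing_assays=(),
    seed: int | None = None,
) -> pd.DataFrame:
    """CT table for an extended validation cohort.

    Underlying expression is re-simulated from the same truth network for
    ``n_patients`` matched pairs (default ``config.n_qpcr_pairs``); CT is
    an affine decreasing function of log2 expression plus the reference
    gene near 20 cycles. Assays in ``failing_assays`` emulate
    non-amplification: CT above 35 or undefined in most samples. Calls
    that share ``seed`` share the simulated cohort, so miRNA and mRNA
    plates drawn separately stay correlated.
    """
    import zlib

    n_patients = n_patients or config.n_qpcr_pairs
    seed = config.seed if seed is None else seed
    cohort_cfg = replace(config, n_pairs=n_patients, seed=seed)
    # expression draw depends only on (seed, truth, n_patients): two plates
    # generated with the same seed share the underlying cohort, so
    # miRNA/mRNA assays drawn separately stay correlated
    rng_expr = np.random.default_rng([int(seed), _STREAM_QPCR])
    Xdf, Ydf, meta = _simulate_expression(truth, cohort_cfg, rng_expr)
    expr = pd.concat([Xdf, Ydf])
    failing = set(failing_assays)
    rows = []
    for assay in assays:
        if assay not in expr.index:
            raise ValueError(f"assay {assay!r} is not a simulated feature")
        # per-assay noise stream: independent of which other assays share the plate
        rng = np.random.default_rng([int(seed), _STREAM_QPCR, 1, zlib.crc32(assay.encode())])
        for sample in expr.columns:
            ref_ct = float(rng.normal(REF_CT_MEAN, REF_CT_SD))
            if assay in failing:
                ct = float(rng.normal(37.0, 1.0))
                if rng.random() < 0.3:
                    ct = np.nan
            else:
                ct = CT_INTERCEPT - CT_SLOPE * float(expr.loc[assay, sample]) + float(
                    rng.normal(0.0, 0.2)
                )
            rows.append(
                {
                    "sample_id": sample,
                    "patient_id": meta.loc[sample, "patient_id"],
                    "group": meta.loc[sample, "group"],
                    "assay_id": assay,
                    "ct": ct,
                    "ref_ct": ref_ct,
                }
            )
    return pd.DataFrame(rows)


def write_qpcr_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")
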
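"""Target prediction: seed-site matching, complementarity scoring, tables.

Two algorithmic prediction sources stand in for database lookups so the
dual-source criterion works offline:

* a seed matcher reporting canonical site classes (8mer, 7mer-m8,
  7mer-A1, 6mer) of the miRNA seed (positions 2-8 from the 5' end) on the
  3'UTR sense strand, and
* a local complementarity aligner (Smith-Waterman with affine gaps,
  G:U wobble allowed, seed positions weighted) in the spirit of miRanda.

External 2-column prediction tables are equally accepted; the pipeline's
contract is only "supported by two named sources".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SeedSite",
    "PredictionSource",
    "MirandaParams",
    "AlignmentResult",
    "find_seed_sites",
    "miranda_like_score",
    "load_prediction_table",
    "write_prediction_table",
    "intersect_sources",
    "identify_regulatory_pairs",
    "predict_from_sequences",
]

_RNA = set("ACGU")
_DNA = set("ACGT")
_COMP_DNA = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}

SITE_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer")


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class SeedSite:
    """One seed-match locus on a UTR (0-based, half-open, sense strand)."""

    mirna_id: str
    utr_id: str
    start: int
    end: int
    site_type: str
    pattern: str


@dataclass
class PredictionSource:
    name: str
    pairs: set
    provenance: str = "external_table"


def _check_alphabet(seq: str, alphabet: set, label: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise SequenceError(f"invalid {label} base {ch!r} at position {i}")
    return seq


def _revcomp_dna(seq: str) -> str:
    """Reverse complement of an RNA/DNA string, emitted as DNA."""
    return "".join(_COMP_DNA[c] for c in reversed(seq))


def seed_patterns(mirna_seq: str) -> dict:
    """UTR sense-strand match patterns derived from the miRNA seed.

    The 6mer core is the reverse complement of miRNA positions 2-7;
    7mer-m8 adds the complement of position 8 on the 5' side; 7mer-A1
    adds an A on the 3' side; 8mer has both.
    """
    m = _check_alphabet(mirna_seq, _RNA, "miRNA")
    if len(m) < 8:
        raise SequenceError("miRNA must be at least 8 nt")
    core = _revcomp_dna(m[1:7])          # positions 2-7
    m8 = _COMP_DNA[m[7]]                 # complement of position 8
    return {
        "6mer": core,
        "7mer-A1": core + "A",
        "7mer-m8": m8 + core,
        "8mer": m8 + core + "A",
    }


def find_seed_sites(mirna_seq: str, utr_seq: str, mirna_id: str = "", utr_id: str = "") -> list:
    """All seed-match loci, each reported once with its strongest type.

    Loci are anchored on the 6mer core; flanking matches upgrade the type
    (8mer > 7mer-m8 > 7mer-A1 > 6mer). Coordinates span the full pattern.
    """
    pat = seed_patterns(mirna_seq)
    utr = _check_alphabet(utr_seq, _DNA, "UTR")
    core = pat["6mer"]
    sites = []
    j = utr.find(core)
    while j != -1:
        has_m8 = j > 0 and utr[j - 1] == pat["7mer-m8"][0]
        has_a1 = j + 6 < len(utr) and utr[j + 6] == "A"
        if has_m8 and has_a1:
            st, start, end = "8mer", j - 1, j + 7
        elif has_m8:
            st, start, end = "7mer-m8", j - 1, j + 6
        elif has_a1:
            st, start, end = "7mer-A1", j, j + 7
        else:
            st, start, end = "6mer", j, j + 6
        sites.append(
            SeedSite(mirna_id, utr_id, start, end, st, utr[start:end])
        )
        j = utr.find(core, j + 1)
    return sites


# ---------------------------------------------------------------------
# miRanda-like local alignment

@dataclass(frozen=True)
class MirandaParams:
    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_weight: float = 2.0    # multiplier on substitution scores at miRNA positions 2-8
    threshold: float = 100.0


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    utr_start: int
    utr_end: int

    @property
    def window(self):
        return (self.utr_start, self.utr_end)


def _pair_score(mi: str, ut: str, params: MirandaParams) -> float:
    """Complementarity score of one miRNA base against one UTR base."""
    wc = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
    wobble = {("G", "T"), ("U", "G")}
    if (mi, ut) in wc:
        return params.match
    if (mi, ut) in wobble:
        return params.wobble
    return params.mismatch


def miranda_like_score(mirna_seq: str, utr_seq: str, params: MirandaParams | None = None) -> AlignmentResult:
    """Best local complementarity alignment (miRNA 3'->5' vs UTR 5'->3').

    Gotoh affine-gap Smith-Waterman; substitution scores at miRNA seed
    positions (2-8, 1-based from the 5' end) are multiplied by
    ``seed_weight``. The score floor is 0 (empty local alignment).
    """
    params = params or MirandaParams()
    m = _check_alphabet(mirna_seq, _RNA, "miRNA")
    u = _check_alphabet(utr_seq, _DNA, "UTR")
    # align the miRNA reversed so its 3' end meets the UTR 5' side
    mr = m[::-1]
    # original (1-based) miRNA position of each reversed index
    pos = [len(m) - i for i in range(len(mr))]
    NEG = -1e18
    nm, nu = len(mr), len(u)
    M = np.zeros((nm + 1, nu + 1))
    Ix = np.full((nm + 1, nu + 1), NEG)  # gap in UTR (miRNA consumed)
    Iy = np.full((nm + 1, nu + 1), NEG)  # gap in miRNA (UTR consumed)
    best, best_cell = 0.0, (0, 0)
    for i in range(1, nm + 1):
        w = params.seed_weight if 2 <= pos[i - 1] <= 8 else 1.0
        for j in range(1, nu + 1):
            sub = w * _pair_score(mr[i - 1], u[j - 1], params)
            diag = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1], 0.0)
            M[i, j] = diag + sub
            Ix[i, j] = max(M[i - 1, j] + params.gap_open, Ix[i - 1, j] + params.gap_extend)
            Iy[i, j] = max(M[i, j - 1] + params.gap_open, Iy[i, j - 1] + params.gap_extend)
            here = max(M[i, j], Ix[i, j], Iy[i, j])
            if here > best:
                best, best_cell = here, (i, j)
    if best <= 0:
        return AlignmentResult(0.0, 0, 0)
    # traceback for the UTR window only
    i, j = best_cell
    state = max((M[i, j], "M"), (Ix[i, j], "Ix"), (Iy[i, j], "Iy"))[1]
    end_j = j
    while i > 0 and j > 0:
        if state == "M":
            prev = max((M[i - 1, j - 1], "M"), (Ix[i - 1, j - 1], "Ix"), (Iy[i - 1, j - 1], "Iy"), (0.0, "stop"))[1]
            i, j = i - 1, j - 1
            if prev == "stop":
                break
            state = prev
        elif state == "Ix":
            state = "M" if Ix[i, j] == M[i - 1, j] + params.gap_open else "Ix"
            i -= 1
        else:
            state = "M" if Iy[i, j] == M[i, j - 1] + params.gap_open else "Iy"
            j -= 1
    return AlignmentResult(float(best), j, end_j)


# ---------------------------------------------------------------------
# sources and intersection

def load_prediction_table(path, name: str) -> PredictionSource:
    """Read a 2-column (mirna_id, mrna_id) TSV; '#' lines and an optional
    'mirna_id<TAB>mrna_id' column header are skipped; duplicates collapse."""
    pairs = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:2] == ["mirna_id", "mrna_id"]:
                continue
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            pairs.add((fields[0], fields[1]))
    return PredictionSource(name=name, pairs=pairs, provenance="external_table")


def write_prediction_table(source: PredictionSource, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# source={source.name}\n")
        fh.write("mirna_id\tmrna_id\n")
        for mi, mr in sorted(source.pairs):
            fh.write(f"{mi}\t{mr}\n")


def predict_from_sequences(
    mirna_seqs: dict,
    utr_seqs: dict,
    method: str = "seed",
    site_types: tuple = ("8mer", "7mer-m8", "7mer-A1"),
    params: MirandaParams | None = None,
    name: str | None = None,
) -> PredictionSource:
    """Build a prediction source by scanning sequences.

    ``method='seed'`` predicts a pair when the UTR carries at least one
    site of an allowed type (6mer excluded by default: weak sites inflate
    false positives); ``method='align'`` uses the miRanda-like score
    threshold.
    """
    pairs = set()
    if method == "seed":
        for mi, ms in mirna_seqs.items():
            for ut, us in utr_seqs.items():
                if any(s.site_type in site_types for s in find_seed_sites(ms, us, mi, ut)):
                    pairs.add((mi, ut))
        return PredictionSource(name or "seed_match", pairs, "seed_match")
    if method == "align":
        p = params or MirandaParams()
        for mi, ms in mirna_seqs.items():
            for ut, us in utr_seqs.items():
                if miranda_like_score(ms, us, p).score >= p.threshold:
                    pairs.add((mi, ut))
        return PredictionSource(name or "alignment", pairs, "alignment_score")
    raise ValueError(f"unknown method {method!r}")


def intersect_sources(a: PredictionSource, b: PredictionSource) -> set:
    return a.pairs & b.pairs


def identify_regulatory_pairs(retained: pd.DataFrame, both: set):
    """Final pairs: retained anti-correlated pairs that both sources predict.

    Returns ``(final, summary)`` where ``final`` is the retained-pair
    frame restricted to dual-source support and ``summary`` the headline
    counts (pair total, distinct miRNAs/mRNAs, per-arm breakdown).
    """
    if len(retained) == 0:
        final = retained.copy()
    else:
        sel = retained.apply(
            lambda row: bool(row.get("retained", True)) and (row["mirna_id"], row["mrna_id"]) in both,
            axis=1,
        )
        final = retained[sel].reset_index(drop=True)
    up_down = int(((final.get("mirna_direction") == "up") & (final.get("mrna_direction") == "down")).sum()) if len(final) else 0
    down_up = int(((final.get("mirna_direction") == "down") & (final.get("mrna_direction") == "up")).sum()) if len(final) else 0
    summary = {
        "n_pairs": int(len(final)),
        "n_mirnas": int(final["mirna_id"].nunique()) if len(final) else 0,
        "n_mrnas": int(final["mrna_id"].nunique()) if len(final) else 0,
        "up_mirna_down_mrna": up_down,
        "down_mirna_up_mrna": down_up,
    }
    return final, summary


def write_sites(sites: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tutr_id\tstart\tend\tsite_type\tpattern\n")
        for s in sites:
            fh.write(f"{s.mirna_id}\t{s.utr_id}\t{s.start}\t{s.end}\t{s.site_type}\t{s.pattern}\n")
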
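"""Genomic consensus around called cap-m6Am TSSs.

Flanks of 46 nt (40 upstream, the TSS base, 5 downstream, all in the
transcription direction) are collapsed into a position probability
matrix; the summary report checks the hallmarks of cap methylation in
genomic context: the methylated A at the start base, the C at -1 (a
pyrimidine bias), a non-A "B" base at -2 — the BCA consensus — and a
TATA tetramer in the -35..-25 region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["FLANK_UP", "FLANK_DOWN", "FLANK_LEN",
           "PositionProbabilityMatrix", "extract_flanks", "build_ppm",
           "consensus_report", "ppm_to_frame"]

FLANK_UP = 40
FLANK_DOWN = 5
FLANK_LEN = FLANK_UP + 1 + FLANK_DOWN   # offsets -40 .. +5, TSS at 0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"


@dataclass
class PositionProbabilityMatrix:
    offsets: np.ndarray        # -40 .. +5
    probs: np.ndarray          # (46, 4) over A, C, G, T
    n_sequences: int
    info_content: np.ndarray   # per-offset bits in [0, 2]

    def prob(self, offset: int, base: str) -> float:
        i = int(np.where(self.offsets == offset)[0][0])
        return float(self.probs[i, _BASES.index(base)])


def extract_flanks(genes, catalog, genome: dict, truth_tss: dict | None = None
                   ) -> list[str]:
    """Strand-aware 46-mers around each gene's called TSS.

    ``genes`` may be a set/list of gene ids or a CallSet; one flank per
    gene is taken at its called TSS (or at ``truth_tss[gene]`` when a
    specific TSS id is supplied).  Minus-strand flanks are
    reverse-complemented so offset 0 is always the first transcribed
    base.  Flanks running past a contig edge are skipped with a warning.
    """
    if hasattr(genes, "passed_genes"):   # CallSet
        wanted = {}
        for c in genes.calls:
            if c.passed:
                wanted[c.window.tss.gene_id] = c.window.tss.tss_id
    else:
        wanted = {g: (truth_tss or {}).get(g) for g in genes}

    by_gene: dict[str, list] = {}
    for rec in catalog:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    flanks: list[str] = []
    for gene_id in sorted(wanted):
        recs = by_gene.get(gene_id)
        if not recs:
            warnings.warn(f"gene {gene_id} absent from the TSS catalog")
            continue
        tss_id = wanted[gene_id]
        rec = next((r for r in recs if r.tss_id == tss_id), recs[0])
        seq = genome.get(rec.chrom)
        if seq is None:
            warnings.warn(f"chromosome {rec.chrom} absent from the genome")
            continue
        if rec.strand == "+":
            lo, hi = rec.pos - FLANK_UP, rec.pos + FLANK_DOWN + 1
            if lo < 0 or hi > len(seq):
                warnings.warn(f"TSS {gene_id}|{rec.tss_id} too close to a "
                              f"contig edge; flank skipped")
                continue
            flanks.append(seq[lo:hi].upper())
        else:
            lo, hi = rec.pos - FLANK_DOWN, rec.pos + FLANK_UP + 1
            if lo < 0 or hi > len(seq):
                warnings.warn(f"TSS {gene_id}|{rec.tss_id} too close to a "
                              f"contig edge; flank skipped")
                continue
            flanks.append(seq[lo:hi].upper().translate(_COMPLEMENT)[::-1])
    return flanks


def build_ppm(flanks) -> PositionProbabilityMatrix:
    """Column-wise base probabilities and information content (bits).

    ``N`` bases are excluded per column rather than discarding the whole
    sequence; information content is 2 minus the Shannon entropy of the
    column distribution.
    """
    flanks = list(flanks)
    if not flanks:
        raise ValueError("need at least one flank sequence")
    if any(len(f) != FLANK_LEN for f in flanks):
        bad = next(f for f in flanks if len(f) != FLANK_LEN)
        raise ValueError(f"flanks must all be {FLANK_LEN} nt, "
                         f"got one of length {len(bad)}")
    arr = np.frombuffer("".join(flanks).encode(), dtype="S1")
    arr = arr.reshape(len(flanks), FLANK_LEN)
    counts = np.zeros((FLANK_LEN, 4))
    for j, base in enumerate(_BASES):
        counts[:, j] = (arr == base.encode()).sum(axis=0)
    valid = counts.sum(axis=1)
    if (valid == 0).any():
        raise ValueError("a column contains only N bases")
    probs = counts / valid[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return PositionProbabilityMatrix(
        offsets=np.arange(-FLANK_UP, FLANK_DOWN + 1),
        probs=probs, n_sequences=len(flanks),
        info_content=np.clip(info, 0.0, 2.0))


def consensus_report(ppm: PositionProbabilityMatrix,
                     flanks=None) -> dict:
    """Fractions at the consensus-defining offsets, plus the maximal
    TATA tetramer match frequency for starts in -35..-25.

    When the flank sequences are supplied, the TATA frequency is the
    exact fraction of sequences containing a TATA starting in that
    range; otherwise it is estimated from the PPM as the product of
    per-position probabilities, which understates it when the TATA
    anchor varies between sequences.
    """
    report = {
        "a_at_0": ppm.prob(0, "A"),
        "pyrimidine_at_-1": ppm.prob(-1, "C") + ppm.prob(-1, "T"),
        "c_at_-1": ppm.prob(-1, "C"),
        "non_a_at_-2": 1.0 - ppm.prob(-2, "A"),
    }
    if flanks is not None:
        hits = 0
        n = 0
        for seq in flanks:
            n += 1
            window = seq[FLANK_UP - 35:FLANK_UP - 25 + 4]
            if "TATA" in window:
                hits += 1
        report["tata_match_upstream"] = hits / n if n else 0.0
    else:
        best = 0.0
        for start in range(-35, -25 + 1):
            prob = 1.0
            for k, base in enumerate("TATA"):
                prob *= ppm.prob(start + k, base)
            best = max(best, prob)
        report["tata_match_upstream"] = best
    report["n_sequences"] = ppm.n_sequences
    return report


def ppm_to_frame(ppm: PositionProbabilityMatrix):
    import pandas as pd
    return pd.DataFrame({
        "offset": ppm.offsets,
        "pA": ppm.probs[:, 0], "pC": ppm.probs[:, 1],
        "pG": ppm.probs[:, 2], "pT": ppm.probs[:, 3],
        "bits": ppm.info_content,
        "n": ppm.n_sequences}).set_index("offset")
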
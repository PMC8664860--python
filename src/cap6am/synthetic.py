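"""Synthetic data with planted ground truth for every pipeline input.

The generator emulates the data a cap-m6Am mapping experiment produces
*after* alignment: per-position read 5'-end count tracks for IP and input
libraries, a TSS catalog, a genome carrying the BCA consensus and an
upstream TATA at methylated start sites, expression / ribosome / half-life
/ protein tables in which methylation status shifts the distribution, a
peptide intensity table with known protein abundances, and external-caller
peaks.  Everything is driven by one master seed; per-file child streams
are derived by labeled hashing, so a fixed :class:`SimulationConfig`
yields byte-identical outputs.

What is emulated and what is not: counts are Poisson per transcribed
position with multiplicative IP enrichment over the planted 25-nt TSS
window, plus spike inflation at a configurable fraction of positions to
exercise the duplicate cap.  There is no read-level error model, no
alignment artifacts, no mappability structure, no over-dispersion beyond
the duplicate spikes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (EndCountTrack, PeakRecord, TSSRecord, write_end_counts,
                 write_fasta, write_narrowpeak, write_tss_bed)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_annotation",
           "simulate_truth", "simulate_genome", "simulate_end_counts",
           "simulate_expression_tables", "simulate_peptides",
           "simulate_external_peaks", "simulate_all", "write_outputs"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulated experiment.

    Defaults describe a liver-scale two-condition comparison scaled to
    desk size: 1,000 genes, 10% of them cap-methylated per condition,
    8-fold mean IP enrichment over the TSS window, one million read ends
    per library, three replicates per condition.
    """

    n_genes: int = 1000
    alt_tss_prob: float = 0.2          # chance of a second, downstream TSS
    frac_methylated: float = 0.10      # per-condition m6Am-positive fraction
    enrichment_fold: float = 8.0       # mean IP/input enrichment at planted TSS
    depth_ip: int = 1_000_000          # expected IP library size (read ends)
    depth_input: int = 1_000_000
    dup_rate: float = 0.01             # fraction of covered positions spiked
    n_replicates: int = 3
    background_rate: float = 1.0       # expected end count per position
    effect_expression: float = 2.0     # multiplicative shift, methylated genes
    effect_protein: float = 2.0
    seed: int = 0
    # secondary knobs
    conditions: tuple = ("lean", "fat")
    # fraction of condition-A's methylated set retained in condition B;
    # 0.46 makes ~30% of the two-set union shared, i.e. ~70% of
    # methylated genes condition-specific
    condition_overlap: float = 0.46
    gene_length: int = 1000
    genes_per_chrom: int = 50
    margin: int = 100                  # intergenic spacing / edge margin
    tata_prob: float = 0.9             # chance of a TATA 25-35 bp upstream
    internal_peak_frac: float = 0.5    # genes carrying an internal m6A peak
    peptides_min: int = 2
    peptides_max: int = 10
    peptide_noise: float = 0.2         # lognormal sigma on peptide intensity
    nonunique_frac: float = 0.1
    n_protein_samples: int = 2         # per condition

    def __post_init__(self) -> None:
        for name in ("alt_tss_prob", "frac_methylated", "dup_rate",
                     "condition_overlap", "tata_prob", "internal_peak_frac",
                     "nonunique_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "depth_ip", "depth_input", "n_replicates",
                     "gene_length", "genes_per_chrom"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.enrichment_fold < 1.0:
            raise ValueError("enrichment_fold must be >= 1")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")

    def rng(self, *labels) -> np.random.Generator:
        """Deterministic child stream keyed by a label tuple."""
        key = "/".join(str(x) for x in labels)
        child = zlib.crc32(key.encode()) & 0x7FFFFFFF
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, child])


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int            # 0-based half-open genomic span of the gene body
    end: int
    strand: str
    tss_list: list = field(default_factory=list)  # TSSRecord, primary first

    def transcribed_positions(self) -> np.ndarray:
        pos = np.arange(self.start, self.end, dtype=np.int64)
        return pos if self.strand == "+" else pos[::-1]


@dataclass
class GroundTruth:
    """The planting record: what was simulated where."""

    methylated: dict            # condition -> set of gene ids
    planted_tss: dict           # gene id -> tss_id used for the enrichment
    enrichment: dict            # gene id -> fold
    expression: dict            # gene id -> base expression level
    protein: dict               # protein id -> {sample: true abundance}

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.expression)
        rows = []
        for g in genes:
            rows.append({
                "gene": g,
                **{f"methylated_{c}": int(g in s)
                   for c, s in self.methylated.items()},
                "planted_tss": self.planted_tss.get(g, ""),
                "enrichment": self.enrichment.get(g, 1.0),
                "expression": self.expression[g],
            })
        return pd.DataFrame(rows).set_index("gene")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, protein: dict | None = None):
        meth = {}
        for col in df.columns:
            if col.startswith("methylated_"):
                cond = col[len("methylated_"):]
                meth[cond] = set(df.index[df[col] == 1])
        planted = {g: t for g, t in df["planted_tss"].items()
                   if isinstance(t, str) and t}
        any_meth = set().union(*meth.values()) if meth else set()
        return cls(methylated=meth, planted_tss=planted,
                   enrichment={g: f for g, f in df["enrichment"].items()
                               if g in any_meth},
                   expression=df["expression"].to_dict(),
                   protein=protein or {})


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig):
    """Lay out non-overlapping gene bodies on linear chromosomes.

    Genes alternate strands; each carries one primary TSS at the 5' end of
    its body and, with probability ``alt_tss_prob``, a second TSS offset
    20-200 bp downstream in the transcription direction.
    """
    rng = config.rng("annotation")
    genes: list[GeneModel] = []
    catalog: list[TSSRecord] = []
    for i in range(config.n_genes):
        chrom = f"chr{i // config.genes_per_chrom + 1}"
        slot = i % config.genes_per_chrom
        start = config.margin + slot * (config.gene_length + config.margin)
        end = start + config.gene_length
        strand = "+" if i % 2 == 0 else "-"
        gene_id = f"G{i:04d}"
        gene = GeneModel(gene_id=gene_id, chrom=chrom, start=start,
                         end=end, strand=strand)
        primary_pos = start if strand == "+" else end - 1
        gene.tss_list.append(TSSRecord(
            chrom=chrom, pos=primary_pos, strand=strand, gene_id=gene_id,
            tss_id="t1", source="refseq-like"))
        if rng.random() < config.alt_tss_prob:
            offset = int(rng.integers(20, 201))
            alt_pos = (primary_pos + offset if strand == "+"
                       else primary_pos - offset)
            gene.tss_list.append(TSSRecord(
                chrom=chrom, pos=alt_pos, strand=strand, gene_id=gene_id,
                tss_id="t2", source="epd-like"))
        genes.append(gene)
        catalog.extend(gene.tss_list)
    return genes, catalog


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig, truth: GroundTruth,
                    genes: list[GeneModel]) -> dict[str, str]:
    """Uniform-random genome with the cap consensus planted at methylated
    TSSs: transcribed ``A`` at the start base, ``C`` at -1, ``B`` (G/C/T)
    at -2, and a TATA tetramer 25-35 bp upstream with ``tata_prob``."""
    rng = config.rng("genome")
    chrom_len: dict[str, int] = {}
    for g in genes:
        chrom_len[g.chrom] = max(chrom_len.get(g.chrom, 0),
                                 g.end + config.margin)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    chromosomes = {c: rng.integers(0, 4, size=n)
                   for c, n in chrom_len.items()}

    methylated_any = set().union(*truth.methylated.values()) \
        if truth.methylated else set()
    base_index = {b: i for i, b in enumerate("ACGT")}

    def plant(chrom: str, tss: TSSRecord, motif: dict[int, str]) -> None:
        """Write transcribed-space bases (offset -> base) into the genome."""
        arr = chromosomes[chrom]
        for offset, base in motif.items():
            if tss.strand == "+":
                gpos, gbase = tss.pos + offset, base
            else:
                gpos = tss.pos - offset
                gbase = base.translate(_COMPLEMENT)
            if not 0 <= gpos < len(arr):
                raise ValueError(
                    f"TSS {tss.gene_id}|{tss.tss_id} too close to the "
                    f"contig edge for motif planting")
            arr[gpos] = base_index[gbase]

    for g in genes:
        if g.gene_id not in methylated_any:
            continue
        tss_id = truth.planted_tss.get(g.gene_id, "t1")
        tss = next(t for t in g.tss_list if t.tss_id == tss_id)
        if min(tss.pos, len(chromosomes[g.chrom]) - 1 - tss.pos) < 45:
            raise ValueError(
                f"TSS {g.gene_id}|{tss_id} within 45 bp of a contig edge")
        motif = {0: "A", -1: "C",
                 -2: str(rng.choice(list("GCT")))}
        if rng.random() < config.tata_prob:
            anchor = -int(rng.integers(28, 36))  # TATA start offset
            for k, b in enumerate("TATA"):
                motif[anchor + k] = b
        plant(g.chrom, tss, motif)

    return {c: bases[a].tobytes().decode() for c, a in chromosomes.items()}


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def simulate_truth(config: SimulationConfig,
                   genes: list[GeneModel]) -> GroundTruth:
    rng = config.rng("truth")
    gene_ids = [g.gene_id for g in genes]
    n_meth = int(round(config.frac_methylated * config.n_genes))
    methylated: dict[str, set] = {}
    first_set: list[str] | None = None
    for cond in config.conditions:
        if first_set is None:
            chosen = list(rng.choice(gene_ids, size=n_meth, replace=False))
            first_set = chosen
        else:
            n_common = int(round(config.condition_overlap * n_meth))
            common = list(rng.choice(first_set, size=n_common, replace=False))
            pool = [g for g in gene_ids if g not in set(first_set)]
            fresh = list(rng.choice(pool, size=n_meth - n_common,
                                    replace=False))
            chosen = common + fresh
        methylated[cond] = set(chosen)

    all_meth = set().union(*methylated.values()) if methylated else set()
    by_id = {g.gene_id: g for g in genes}
    planted_tss = {gid: by_id[gid].tss_list[0].tss_id for gid in all_meth}
    enrichment = {gid: float(config.enrichment_fold) for gid in all_meth}
    expression = {gid: float(x) for gid, x in zip(
        gene_ids, rng.lognormal(mean=np.log(100.0), sigma=1.0,
                                size=len(gene_ids)))}
    return GroundTruth(methylated=methylated, planted_tss=planted_tss,
                       enrichment=enrichment, expression=expression,
                       protein={})


# ---------------------------------------------------------------------------
# End-count tracks
# ---------------------------------------------------------------------------

def _tss_window_positions(tss: TSSRecord, width: int) -> np.ndarray:
    if tss.strand == "+":
        return np.arange(tss.pos, tss.pos + width, dtype=np.int64)
    return np.arange(tss.pos - width + 1, tss.pos + 1, dtype=np.int64)


def simulate_end_counts(config: SimulationConfig, truth: GroundTruth,
                        genes: list[GeneModel], condition: str,
                        replicate: int, role: str,
                        window: int = 25) -> EndCountTrack:
    """Poisson end counts over transcribed positions.

    Per-position rate is ``background_rate`` scaled so the expected
    background library equals the configured depth; for ``role="ip"``
    the planted 25-nt window of each methylated gene is multiplied by the
    gene's enrichment fold.  ``dup_rate`` of covered positions receive a
    spike (count forced above the duplicate cap).  ``library_size`` is
    the pre-cap sum of emitted ends.
    """
    if role not in ("ip", "input"):
        raise ValueError(f"role must be 'ip' or 'input', got {role!r}")
    if condition not in truth.methylated:
        raise KeyError(f"condition {condition!r} not present in ground truth")
    rng = config.rng("ends", condition, replicate, role)
    depth = config.depth_ip if role == "ip" else config.depth_input
    n_positions = config.n_genes * config.gene_length
    scale = depth / (config.background_rate * n_positions)
    methylated = truth.methylated[condition]

    # genes do not overlap, so per-(chrom, strand) position arrays are
    # unique and can be concatenated then sorted once
    chunks: dict = {}
    total = 0
    for g in genes:
        positions = np.arange(g.start, g.end, dtype=np.int64)
        rate = np.full(positions.shape, config.background_rate * scale)
        if role == "ip" and g.gene_id in methylated:
            tss = next(t for t in g.tss_list
                       if t.tss_id == truth.planted_tss[g.gene_id])
            win = _tss_window_positions(tss, window)
            mask = (positions >= win.min()) & (positions <= win.max())
            rate[mask] *= truth.enrichment[g.gene_id]
        counts = rng.poisson(rate)
        if config.dup_rate > 0:
            covered = np.flatnonzero(counts > 0)
            if covered.size:
                spiked = covered[rng.random(covered.size) < config.dup_rate]
                counts[spiked] += 6 + rng.poisson(10.0, size=spiked.size)
        nz = np.flatnonzero(counts)
        total += int(counts.sum())
        chunks.setdefault((g.chrom, g.strand), []).append(
            (positions[nz], counts[nz].astype(np.int64)))

    track_counts = {}
    for key, parts in chunks.items():
        pos = np.concatenate([p for p, _ in parts])
        val = np.concatenate([v for _, v in parts])
        order = np.argsort(pos, kind="stable")
        track_counts[key] = (pos[order], val[order])
    sample_id = f"{condition}-rep{replicate}-{role}"
    return EndCountTrack(sample_id=sample_id, role=role,
                         library_size=total, counts=track_counts)


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

def simulate_expression_tables(config: SimulationConfig, truth: GroundTruth):
    """Expression / ribosome / half-life / protein tables.

    Log-normal draws around each gene's true level; genes methylated in a
    condition have their draws in that condition's samples multiplied by
    the configured effect.  Returns four DataFrames indexed by gene with
    one column per ``condition-repN`` sample.
    """
    rng = config.rng("tables")
    genes = sorted(truth.expression)
    base = np.array([truth.expression[g] for g in genes])
    out = {}
    effects = {"expression": config.effect_expression,
               "ribosome": config.effect_expression,
               "halflife": config.effect_expression,
               "protein": config.effect_protein}
    for name, effect in effects.items():
        cols = {}
        for cond in config.conditions:
            meth = np.array([g in truth.methylated[cond] for g in genes])
            for rep in range(1, config.n_replicates + 1):
                draw = base * rng.lognormal(mean=0.0, sigma=0.25,
                                            size=len(genes))
                draw = np.where(meth, draw * effect, draw)
                cols[f"{cond}-rep{rep}"] = draw
        out[name] = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))

    # true per-sample protein abundances feed the peptide simulator
    truth.protein = {
        g: {f"{cond}-s{j}": float(
                truth.expression[g] *
                (config.effect_protein if g in truth.methylated[cond] else 1.0))
            for cond in config.conditions
            for j in range(1, config.n_protein_samples + 1)}
        for g in genes}
    return (out["expression"], out["ribosome"], out["halflife"],
            out["protein"])


def simulate_peptides(config: SimulationConfig,
                      truth: GroundTruth) -> pd.DataFrame:
    """Peptide intensity table: 2-10 peptides per protein, intensities
    proportional to the true abundance with multiplicative log-normal
    noise; ``nonunique_frac`` of peptides flagged non-unique; per-sample
    totals deliberately unequal so TIC normalization is non-trivial."""
    if not truth.protein:
        raise ValueError("ground truth has no protein abundances; run "
                         "simulate_expression_tables first")
    rng = config.rng("peptides")
    samples = sorted(next(iter(truth.protein.values())))
    sample_scale = {s: float(rng.lognormal(0.0, 0.5)) for s in samples}
    rows = []
    for protein in sorted(truth.protein):
        n_pep = int(rng.integers(config.peptides_min, config.peptides_max + 1))
        for k in range(n_pep):
            # peptide_noise=0 means fully noise-free: intensity exactly
            # proportional to abundance (ionization efficiency 1)
            ionization = (float(rng.lognormal(0.0, 0.5))
                          if config.peptide_noise > 0 else 1.0)
            unique = int(rng.random() >= config.nonunique_frac)
            row = {"peptide": f"{protein}_p{k + 1}", "protein": protein,
                   "unique": unique}
            for s in samples:
                noise = (float(rng.lognormal(0.0, config.peptide_noise))
                         if config.peptide_noise > 0 else 1.0)
                row[s] = truth.protein[protein][s] * ionization * \
                    sample_scale[s] * noise
            rows.append(row)
    return pd.DataFrame(rows).set_index("peptide")


# ---------------------------------------------------------------------------
# External-caller peaks
# ---------------------------------------------------------------------------

def simulate_external_peaks(config: SimulationConfig, truth: GroundTruth,
                            genes: list[GeneModel],
                            condition: str | None = None) -> list[PeakRecord]:
    """One peak starting at each methylated TSS, plus internal peaks
    > 50 nt downstream for ``internal_peak_frac`` of genes."""
    rng = config.rng("peaks", condition or "all")
    cond = condition or config.conditions[0]
    if cond not in truth.methylated:
        raise KeyError(f"condition {cond!r} not present in ground truth")
    methylated = truth.methylated[cond]
    peaks: list[PeakRecord] = []
    for g in genes:
        if g.gene_id in methylated:
            tss = next(t for t in g.tss_list
                       if t.tss_id == truth.planted_tss[g.gene_id])
            fold = truth.enrichment[g.gene_id] * float(rng.lognormal(0, 0.2))
            width = 50
            start = tss.pos if tss.strand == "+" else tss.pos - width + 1
            peaks.append(PeakRecord(
                chrom=g.chrom, start=start, end=start + width,
                name=f"{g.gene_id}_cap", fold_enrichment=fold,
                q_value=1e-4, summit_offset=width // 2))
        if rng.random() < config.internal_peak_frac:
            offset = int(rng.integers(200, config.gene_length - 200))
            width = 100
            if g.strand == "+":
                start = g.start + offset
            else:
                start = g.end - 1 - offset - width + 1
            peaks.append(PeakRecord(
                chrom=g.chrom, start=start, end=start + width,
                name=f"{g.gene_id}_internal",
                fold_enrichment=float(rng.lognormal(np.log(4), 0.3)),
                q_value=1e-3, summit_offset=width // 2))
    return peaks


# ---------------------------------------------------------------------------
# Whole-study driver
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig) -> dict:
    """Generate every pipeline input in memory; see :func:`write_outputs`."""
    genes, catalog = simulate_annotation(config)
    truth = simulate_truth(config, genes)
    genome = simulate_genome(config, truth, genes)
    tracks = {}
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            for role in ("ip", "input"):
                tracks[(cond, rep, role)] = simulate_end_counts(
                    config, truth, genes, cond, rep, role)
    expr, ribo, halflife, protein = simulate_expression_tables(config, truth)
    peptides = simulate_peptides(config, truth)
    peaks = {cond: simulate_external_peaks(config, truth, genes, cond)
             for cond in config.conditions}
    return {"config": config, "genes": genes, "catalog": catalog,
            "truth": truth, "genome": genome, "tracks": tracks,
            "expression": expr, "ribosome": ribo, "halflife": halflife,
            "protein": protein, "peptides": peptides, "peaks": peaks}


def write_outputs(bundle: dict, outdir) -> dict[str, Path]:
    """Persist a :func:`simulate_all` bundle; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["tss"] = outdir / "tss.bed"
    write_tss_bed(bundle["catalog"], paths["tss"])
    paths["genome"] = outdir / "genome.fa"
    write_fasta(bundle["genome"], paths["genome"])
    for (cond, rep, role), track in bundle["tracks"].items():
        key = f"ends_{cond}_rep{rep}_{role}"
        paths[key] = outdir / f"{key}.tsv"
        write_end_counts(track, paths[key])
    for name in ("expression", "ribosome", "halflife", "protein",
                 "peptides"):
        paths[name] = outdir / f"{name}.tsv"
        bundle[name].to_csv(paths[name], sep="\t")
    for cond, peaks in bundle["peaks"].items():
        key = f"peaks_{cond}"
        paths[key] = outdir / f"{key}.narrowPeak"
        write_narrowpeak(peaks, paths[key])
    paths["truth"] = outdir / "truth.tsv"
    bundle["truth"].to_frame().to_csv(paths["truth"], sep="\t")
    cfg = pd.Series({k: (",".join(map(str, v)) if isinstance(v, tuple) else v)
                     for k, v in asdict(bundle["config"]).items()})
    paths["config"] = outdir / "config_used.tsv"
    cfg.to_csv(paths["config"], sep="\t", header=False)
    return paths
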
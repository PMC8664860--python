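"""End-to-end orchestration: methylome calling across replicates and
conditions, the swapped negative control, and the association report.

All stochastic behavior lives in :mod:`cap6am.synthetic`; given fixed
inputs the stages here are deterministic, and every run emits a manifest
(inputs, parameters, hashes) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import capcall
from .association import (GeneSetPair, de_gain_loss_test, gain_loss,
                          percentile_bin_fractions, rank_compare)
from .capcall import Thresholds, call_sample, negative_control, \
    replicate_consensus, calls_to_frame
from .io import read_end_counts, read_tss_bed

logger = logging.getLogger("cap6am")

__all__ = ["RunConfig", "MethylomeResult", "run_methylome",
           "run_association", "write_manifest"]


@dataclass
class RunConfig:
    """Paths and threshold overrides for a full run.

    ``tracks`` maps condition -> list of ``(ip_path, input_path)`` pairs,
    one per replicate.  Threshold defaults equal the published criteria.
    """

    tss_path: str = ""
    tracks: dict = field(default_factory=dict)
    m1a_path: str | None = None
    expression_path: str | None = None
    protein_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_reps: int = 2
    de_fc_threshold: float = 1.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr_keys = {f.name for f in
                    __import__("dataclasses").fields(Thresholds)}
        thr = Thresholds(**{k: v for k, v in raw.items() if k in thr_keys})
        kwargs = {k: v for k, v in raw.items()
                  if k in {"tss_path", "tracks", "m1a_path",
                           "expression_path", "protein_path", "min_reps",
                           "de_fc_threshold", "seed"}}
        return cls(thresholds=thr, **kwargs)


@dataclass
class MethylomeResult:
    callsets: dict          # condition -> list[CallSet]
    consensus: dict         # condition -> set of gene ids
    negative_counts: dict   # condition -> list[int] per replicate
    forward_counts: dict    # condition -> list[int]


def run_methylome(config: RunConfig, tracks=None, catalog=None,
                  m1a_sites=()) -> MethylomeResult:
    """Call the methylome for every condition and replicate.

    ``tracks``/``catalog`` may be passed in memory (condition ->
    [(ip_track, input_track), ...]); otherwise they are loaded from the
    paths in ``config``.
    """
    if catalog is None:
        catalog = read_tss_bed(config.tss_path)
    if tracks is None:
        tracks = {
            cond: [(read_end_counts(ip), read_end_counts(inp))
                   for ip, inp in pairs]
            for cond, pairs in config.tracks.items()}
    if not tracks:
        raise ValueError("no IP/input track pairs configured")
    for cond, pairs in tracks.items():
        if len(pairs) < config.min_reps:
            raise ValueError(
                f"condition {cond!r} has {len(pairs)} replicates, fewer "
                f"than min_reps={config.min_reps}")

    callsets: dict = {}
    consensus: dict = {}
    neg_counts: dict = {}
    fwd_counts: dict = {}
    for cond, pairs in tracks.items():
        cs_list, neg_list = [], []
        for ip_track, input_track in pairs:
            cs = call_sample(ip_track, input_track, catalog, m1a_sites,
                             config.thresholds)
            neg = negative_control(ip_track, input_track, catalog,
                                   m1a_sites, config.thresholds)
            cs_list.append(cs)
            neg_list.append(len(neg.passed_genes))
        callsets[cond] = cs_list
        consensus[cond] = replicate_consensus(cs_list, config.min_reps)
        neg_counts[cond] = neg_list
        fwd_counts[cond] = [len(cs.passed_genes) for cs in cs_list]
        logger.info("condition %s: consensus %d genes; forward calls %s; "
                    "negative calls %s", cond, len(consensus[cond]),
                    fwd_counts[cond], neg_list)
    return MethylomeResult(callsets=callsets, consensus=consensus,
                           negative_counts=neg_counts,
                           forward_counts=fwd_counts)


def run_association(consensus: dict, expression: pd.DataFrame,
                    conditions: tuple | None = None,
                    protein: pd.DataFrame | None = None,
                    de_fc_threshold: float = 1.5,
                    n_bins: int = 10) -> dict:
    """Association report between two conditions' consensus sets.

    Uses the mean across each condition's sample columns (prefix-matched
    ``<condition>-``) for expression levels and fold changes.
    """
    if conditions is None:
        conditions = tuple(consensus)
    if len(conditions) != 2:
        raise ValueError("association requires exactly two conditions")
    cond_a, cond_b = conditions
    pair = GeneSetPair.of(consensus[cond_a], consensus[cond_b])
    gained, lost, common, spec = gain_loss(pair)

    def cond_mean(df, cond):
        cols = [c for c in df.columns if c.startswith(f"{cond}-")]
        if not cols:
            raise ValueError(f"no sample columns for condition {cond!r}")
        return df[cols].mean(axis=1)

    expr_a = cond_mean(expression, cond_a)
    report: dict = {
        "conditions": (cond_a, cond_b),
        "gained": gained, "lost": lost, "common": common,
        "specificity_fraction": spec,
        "bin_fractions_a": percentile_bin_fractions(
            expr_a, consensus[cond_a], n_bins=n_bins),
    }
    try:
        u, p, med_in, med_out = rank_compare(expr_a, consensus[cond_a])
        report["expression_rank_test"] = {
            "U": u, "p": p, "median_methylated": med_in,
            "median_unmethylated": med_out}
    except ValueError as exc:
        report["expression_rank_test"] = {"error": str(exc)}

    de = cond_mean(expression, cond_b) / expr_a
    if gained or lost:
        try:
            obs, exp, chi2, dof, p = de_gain_loss_test(
                gained, lost, de, fc_threshold=de_fc_threshold)
            report["de_gain_loss"] = {"observed": obs, "expected": exp,
                                      "chi2": chi2, "df": dof, "p": p}
        except ValueError as exc:
            report["de_gain_loss"] = {"error": str(exc)}
    else:
        report["de_gain_loss"] = {"error": "gained and lost sets empty: "
                                           "test undefined"}
    if protein is not None:
        try:
            u, p, med_in, med_out = rank_compare(
                cond_mean(protein, cond_a), consensus[cond_a])
            report["protein_rank_test"] = {
                "U": u, "p": p, "median_methylated": med_in,
                "median_unmethylated": med_out}
        except ValueError as exc:
            report["protein_rank_test"] = {"error": str(exc)}
    return report


def write_manifest(outdir, config: RunConfig, inputs: dict | None = None
                   ) -> Path:
    """Write a JSON manifest of parameters and input hashes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entry: dict = {"thresholds": asdict(config.thresholds),
                   "min_reps": config.min_reps,
                   "de_fc_threshold": config.de_fc_threshold,
                   "seed": config.seed}
    hashes = {}
    for name, path in (inputs or {}).items():
        p = Path(path)
        if p.exists():
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    entry["input_sha256"] = hashes
    try:
        from importlib.metadata import version
        entry["cap6am_version"] = version("cap6am")
    except Exception:
        entry["cap6am_version"] = "unknown"
    path = outdir / "manifest.json"
    path.write_text(json.dumps(entry, indent=2, sort_keys=True))
    return path
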
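"""End-to-end orchestration: mask, search, squeeze, annotate, consense, date.

The search runs on the coding-region mask (default 550..16050, excluding the
hypervariable control region); control-region changes are annotated back onto
the final tree for display and dating but never affect the score or the
minimality certificate.  The report separates "search" sites from
display-only sites and is byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .alignment import (Alignment, AlignmentError, drop_gapped_columns,
                        informative_sites, mask_to_range, read_fasta_alignment)
from .annotate import format_label
from .dating import CalibrationConfig, RhoEstimate, date_named_clades, dating_table
from .parsimony import (MutationMapping, SearchConfig, heuristic_search,
                        map_mutations, strict_consensus)
from .reference import RCRS_LENGTH, load_reference
from .squeeze import SqueezeConfig, squeeze

__version__ = "0.1.0"

logger = logging.getLogger("mtphylo")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for structured errors."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class Finding:
    level: str  # "error" | "warning"
    message: str


@dataclass
class PipelineConfig:
    """All knobs of a run; defaults reproduce the coding-region protocol
    (mask 550..16050, reference rooting, synonymous-clock dating)."""

    input_fasta: str
    output_dir: str = "mtphylo_out"
    mask_lo: int = 550
    mask_hi: int = 16050
    root: str = "reference"  # "reference" or an outgroup taxon label
    clades: dict[str, list[str]] = field(default_factory=dict)
    calibration: str = "kivisild_synonymous"
    soares_years_per_change: Optional[float] = None
    reference_fasta: Optional[str] = None
    gene_map_tsv: Optional[str] = None
    search_max_pool: int = 64
    search_max_evals: int = 2_000_000
    squeeze_max_block_patterns: int = 9
    squeeze_max_pair_checks: int = 2000
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key=value config; clades as ``clade.NAME = leaf1,leaf2``."""
        values: dict = {}
        clades: dict[str, list[str]] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise StageError("config", f"malformed config line: {line!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                if key.startswith("clade."):
                    clades[key[len("clade."):]] = [
                        s.strip() for s in val.split(",") if s.strip()
                    ]
                else:
                    values[key] = val
        cfg = cls(input_fasta=values.pop("input_fasta", ""), clades=clades)
        for key, val in values.items():
            if not hasattr(cfg, key):
                raise StageError("config", f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                val = val.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                val = int(val)
            elif isinstance(current, float) or key == "soares_years_per_change":
                val = float(val)
            setattr(cfg, key, val)
        return cfg

    def calibration_config(self) -> CalibrationConfig:
        if self.calibration == "kivisild_synonymous":
            return CalibrationConfig.kivisild()
        if self.calibration == "soares_complete":
            if self.soares_years_per_change is None:
                raise StageError(
                    "config", "soares_complete needs soares_years_per_change"
                )
            return CalibrationConfig.soares(self.soares_years_per_change)
        raise StageError("config", f"unknown calibration {self.calibration!r}")


def validate_config(cfg: PipelineConfig) -> list[Finding]:
    """Non-throwing config checks; errors and warnings as findings."""
    findings: list[Finding] = []
    if not cfg.input_fasta:
        findings.append(Finding("error", "no input_fasta configured"))
    elif not Path(cfg.input_fasta).exists():
        findings.append(Finding("error", f"input {cfg.input_fasta} not found"))
    if not (1 <= cfg.mask_lo <= cfg.mask_hi <= RCRS_LENGTH):
        findings.append(
            Finding("error", f"mask {cfg.mask_lo}..{cfg.mask_hi} outside 1..{RCRS_LENGTH}")
        )
    if cfg.calibration == "soares_complete" and cfg.soares_years_per_change is None:
        findings.append(
            Finding("error", "soares_complete calibration needs soares_years_per_change")
        )
    if cfg.mask_lo > 1 or cfg.mask_hi < RCRS_LENGTH:
        findings.append(Finding(
            "warning",
            f"positions outside {cfg.mask_lo}..{cfg.mask_hi} (control region) are "
            "excluded from the tree search; their changes are annotated on the "
            "final tree for display and dating only",
        ))
    if cfg.clades and cfg.input_fasta and Path(cfg.input_fasta).exists():
        try:
            aln = read_fasta_alignment(cfg.input_fasta)
            known = set(aln.taxa)
            for name, leaves in cfg.clades.items():
                unknown = set(leaves) - known
                if unknown:
                    findings.append(Finding(
                        "error",
                        f"clade {name!r} names unknown taxa: {sorted(unknown)}",
                    ))
            if cfg.root not in ("reference",) and cfg.root not in known:
                findings.append(Finding("error", f"root taxon {cfg.root!r} not in input"))
        except AlignmentError as exc:
            findings.append(Finding("error", f"input unreadable: {exc}"))
    return findings


@dataclass
class RunReport:
    """Everything the run computed, recomputable from inputs + config + seed."""

    input_digest: str
    n_taxa: int
    mask: tuple[int, int]
    n_search_columns: int
    n_informative: int
    mp_score: int
    n_trees: int
    certificate: dict
    consensus_newick: str
    root_variant_labels: list[str]
    branch_mutation_rows: list[dict]
    dating: list[dict]
    recurrent_positions: dict[int, int]
    version: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "input_digest": self.input_digest,
            "n_taxa": self.n_taxa,
            "mask": list(self.mask),
            "n_search_columns": self.n_search_columns,
            "n_informative": self.n_informative,
            "mp_score": self.mp_score,
            "n_trees": self.n_trees,
            "certificate": self.certificate,
            "consensus_newick": self.consensus_newick,
            "root_variant_labels": self.root_variant_labels,
            "branch_mutations": self.branch_mutation_rows,
            "dating": self.dating,
            "recurrent_positions": {str(k): v for k, v in
                                    sorted(self.recurrent_positions.items())},
            "version": self.version,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _branch_rows(mapping: MutationMapping, lo: int, hi: int) -> list[dict]:
    rows = []
    # name internal nodes deterministically for the table
    counter = 0
    for node in mapping.tree.preorder():
        if node.name is None:
            node.name = f"node{counter}"
            counter += 1
    for node in mapping.tree.preorder():
        for v in node.mutations:
            rows.append({
                "branch": node.name,
                "position": v.position,
                "from": v.ref_base,
                "to": v.obs_base if v.obs_base else "-",
                "kind": v.kind,
                "feature_class": v.feature_class,
                "gene": v.gene,
                "effect": v.coding_effect,
                "label": str(format_label(v)),
                "reversion": bool(v.is_reversion),
                "in_search": bool(lo <= v.position <= hi),
            })
    rows.sort(key=lambda r: (r["branch"], r["position"]))
    return rows


def mutation_table(rows: list[dict]) -> str:
    cols = ["branch", "position", "from", "to", "kind", "feature_class",
            "gene", "effect", "label", "reversion", "in_search"]
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> RunReport:
    """Execute all stages in order; idempotent for a fixed config and seed.

    Raises :class:`StageError` naming the failing stage; when ``write`` is
    set, artifacts produced before a failure stay on disk next to a
    ``FAILED`` marker naming the stage.
    """
    out = Path(cfg.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, exc: Exception) -> StageError:
        if write:
            (out / "FAILED").write_text(f"{stage}: {exc}\n")
        return StageError(stage, str(exc))

    try:
        ref, gene_map = load_reference(cfg.reference_fasta, cfg.gene_map_tsv)
    except Exception as exc:
        raise fail("reference", exc)

    try:
        raw = Path(cfg.input_fasta).read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        aln = read_fasta_alignment(cfg.input_fasta)
        logger.info("[input] %d taxa, %d columns", aln.n_taxa, aln.n_columns)
    except Exception as exc:
        raise fail("input", exc)

    try:
        full = drop_gapped_columns(aln)
        search_aln = drop_gapped_columns(mask_to_range(aln, cfg.mask_lo, cfg.mask_hi))
        report_sites = informative_sites(search_aln)
        logger.info("[mask] %d search columns, %d informative",
                    search_aln.n_columns, report_sites.n_informative)
    except Exception as exc:
        raise fail("mask", exc)

    try:
        ts = heuristic_search(search_aln, SearchConfig(
            max_pool=cfg.search_max_pool, max_evals=cfg.search_max_evals,
            seed=cfg.seed))
        logger.info("[search] score %d, %d equal-best trees", ts.score, len(ts))
    except Exception as exc:
        raise fail("search", exc)

    try:
        probe = map_mutations(ts.trees[0], search_aln, ref, gene_map, root=cfg.root)
        cert = squeeze(
            search_aln, trees=ts,
            recurrent_sites=sorted(probe.recurrent_positions),
            config=SqueezeConfig(
                max_block_patterns=cfg.squeeze_max_block_patterns,
                max_pair_checks=cfg.squeeze_max_pair_checks,
            ),
        )
        logger.info("[squeeze] %s (lower %d, upper %d)",
                    cert.status, cert.lower_bound, cert.upper_bound)
    except Exception as exc:
        raise fail("squeeze", exc)

    try:
        consensus = strict_consensus(ts)
    except Exception as exc:
        raise fail("consense", exc)

    try:
        mapping = map_mutations(consensus, full, ref, gene_map, root=cfg.root)
        rows = _branch_rows(mapping, cfg.mask_lo, cfg.mask_hi)
    except Exception as exc:
        raise fail("annotate", exc)

    try:
        estimates: list[RhoEstimate] = []
        if cfg.clades:
            cal = cfg.calibration_config()
            estimates = date_named_clades(mapping.tree, cfg.clades, cal)
    except Exception as exc:
        raise fail("date", exc)

    report = RunReport(
        input_digest=digest,
        n_taxa=aln.n_taxa,
        mask=(cfg.mask_lo, cfg.mask_hi),
        n_search_columns=search_aln.n_columns,
        n_informative=report_sites.n_informative,
        mp_score=ts.score,
        n_trees=len(ts),
        certificate=cert.to_dict(),
        consensus_newick=consensus.to_newick(),
        root_variant_labels=[str(format_label(v)) for v in mapping.root_variants],
        branch_mutation_rows=rows,
        dating=[e.to_dict() for e in estimates],
        recurrent_positions=mapping.recurrent_positions,
        version=__version__,
        seed=cfg.seed,
    )

    if write:
        search_aln.to_fasta(out / "masked.fasta")
        (out / "trees.json").write_text(json.dumps({
            "score": ts.score,
            "n_trees": len(ts),
            "newicks": [t.to_newick() for t in ts.trees],
        }, indent=2))
        (out / "consensus.nwk").write_text(
            mapping.tree.to_newick(annotations=True) + "\n")
        cert.to_json(out / "certificate.json")
        (out / "mutations.tsv").write_text(mutation_table(rows))
        if estimates:
            (out / "dating.tsv").write_text(dating_table(estimates))
        (out / "report.json").write_text(report.to_json() + "\n")
        marker = out / "FAILED"
        if marker.exists():
            marker.unlink()
    return report
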
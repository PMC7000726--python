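"""Manifest-driven orchestration of the full ortholog-pair comparison.

A manifest is a TSV with one row per ortholog pair (an extremostable
protein, side *a*, and its non-extremostable counterpart, side *b*):

    category  id_a  id_b  fasta_a  fasta_b  pdb_a  pdb_b  chain_a  chain_b

Optional columns may be empty or absent. Sequences come from the PDB
chain when a structure is given (keeping residues and coordinates in
register), otherwise from the FASTA file. Per pair the pipeline
computes composition, physicochemical descriptors and the global
alignment; when both structures are present it adds the refined Cα
RMSD, salt-bridge counts and the ω non-planarity summary. Group-level
output contains per-residue composition t-tests, descriptor t-tests,
occurrence distributions and the per-category Pearson correlation of
alignment identity with RMSD.

An optional resolution ceiling excludes low-resolution structures from
the structural stages only; their sequence-level results are kept.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import align, composition, geometry, physchem, stats, superpose
from .errors import EmptyReportError, ExstabError
from .io import ProteinRecord, Structure, chain_sequence, read_fasta, read_pdb

__all__ = ["PipelineConfig", "ComparisonReport", "run_pair",
           "run_group_analysis", "read_manifest"]

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "category", "id_a", "id_b", "fasta_a", "fasta_b",
    "pdb_a", "pdb_b", "chain_a", "chain_b",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds in one place."""

    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_free: bool = True
    refine: bool = True
    refine_cycles: int = 5
    refine_cutoff: float = 2.0  # Å
    salt_bridge_cutoff: float = 3.2  # Å
    include_his: bool = False
    resolution_max: Optional[float] = None  # Å; None disables the filter
    report_ph: float = 7.0
    t_test_variant: str = "pooled"


@dataclass
class ComparisonReport:
    per_pair: pd.DataFrame
    composition_tests: pd.DataFrame
    descriptor_tests: pd.DataFrame
    correlations: pd.DataFrame
    occurrence_a: Optional[pd.DataFrame]
    occurrence_b: Optional[pd.DataFrame]
    skipped: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "per_pair": json.loads(self.per_pair.to_json(orient="records")),
            "composition_tests": json.loads(
                self.composition_tests.reset_index().to_json(orient="records")),
            "descriptor_tests": json.loads(
                self.descriptor_tests.to_json(orient="records")),
            "correlations": json.loads(
                self.correlations.to_json(orient="records")),
            "skipped": self.skipped,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in ("category", "id_a", "id_b") if c not in df.columns]
    if missing:
        raise ExstabError(f"manifest missing required columns {missing}")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return df


def _load_side(row, side: str, base: Optional[Path]):
    """Returns (record, structure, chain_id) for manifest side a/b."""
    def _path(value: str) -> Path:
        p = Path(value)
        return p if p.is_absolute() or base is None else base / p

    structure: Optional[Structure] = None
    chain_id = (row.get(f"chain_{side}") or "").strip()
    pdb_path = (row.get(f"pdb_{side}") or "").strip()
    fasta_path = (row.get(f"fasta_{side}") or "").strip()
    if pdb_path:
        structure = read_pdb(_path(pdb_path))
        chain_id = chain_id or structure.chains[0].id
        record = chain_sequence(structure, chain_id)
    elif fasta_path:
        records = read_fasta(_path(fasta_path))
        if not records:
            raise ExstabError(f"{fasta_path}: no sequences")
        wanted = row.get(f"id_{side}", "")
        record = next((r for r in records if r.id == wanted), records[0])
    else:
        raise ExstabError(f"row {row.get('id_a')}/{row.get('id_b')}: "
                          f"no input for side {side}")
    return record, structure, chain_id


def _descriptors(record: ProteinRecord, config: PipelineConfig) -> dict:
    profile = physchem.physchem_profile(record, report_ph=config.report_ph)
    return {
        "pI": profile.pI,
        "net_charge_pH7": profile.net_charge_pH7,
        "hydrophobic_pct": profile.hydrophobic_pct,
        "polar_pct": profile.polar_pct,
        "nonpolar_pct": profile.nonpolar_pct,
    }


def _structure_metrics(structure: Structure, chain_id: str,
                       config: PipelineConfig) -> dict:
    chain = structure.chain(chain_id)
    bridges = geometry.find_salt_bridges(
        structure, cutoff=config.salt_bridge_cutoff,
        include_his=config.include_his)
    torsions = geometry.backbone_torsions(chain)
    rama = {"beta": 0, "alpha_R": 0, "alpha_L": 0, "other": 0}
    for rec in torsions:
        if rec.phi is not None and rec.psi is not None:
            rama[geometry.ramachandran_classify(rec.phi, rec.psi)] += 1
    return {
        "salt_bridges": len(bridges),
        "nonplanar_bonds": geometry.count_nonplanar(chain),
        **{f"rama_{k}": v for k, v in rama.items()},
    }


def _passes_resolution(structure: Structure, config: PipelineConfig) -> bool:
    if config.resolution_max is None:
        return True
    return (structure.resolution is not None
            and structure.resolution <= config.resolution_max)


def run_pair(row, config: PipelineConfig = PipelineConfig(),
             base_dir: Optional[Path] = None) -> dict:
    """Full per-pair record; structural fields are NaN when unavailable."""
    record_a, struct_a, chain_a = _load_side(row, "a", base_dir)
    record_b, struct_b, chain_b = _load_side(row, "b", base_dir)

    result: dict = {
        "category": row.get("category", ""),
        "id_a": row.get("id_a") or record_a.id,
        "id_b": row.get("id_b") or record_b.id,
        "length_a": len(record_a),
        "length_b": len(record_b),
    }
    for side, rec in (("a", record_a), ("b", record_b)):
        for key, value in _descriptors(rec, config).items():
            result[f"{key}_{side}"] = value

    aln = align.needleman_wunsch(
        record_a, record_b,
        gap_open=config.gap_open, gap_extend=config.gap_extend,
        end_gaps_free=config.end_gaps_free)
    result.update(
        identity_pct=aln.identity_pct,
        similarity_pct=aln.similarity_pct,
        gaps_pct=aln.gaps_pct,
        alignment_score=aln.score,
    )

    structural = (
        struct_a is not None and struct_b is not None
        and _passes_resolution(struct_a, config)
        and _passes_resolution(struct_b, config)
    )
    result["structural"] = structural
    result["rmsd"] = math.nan
    if structural:
        pairs = superpose.pair_ca_atoms(
            aln, struct_a.chain(chain_a), struct_b.chain(chain_b))
        if config.refine:
            fit = superpose.refine_superposition(
                pairs, cycles=config.refine_cycles,
                reject_cutoff=config.refine_cutoff)
        else:
            fit = superpose.kabsch(pairs)
        result.update(rmsd=fit.rmsd, n_ca_used=fit.n_used,
                      n_ca_rejected=fit.n_rejected)
        for side, st, ch in (("a", struct_a, chain_a), ("b", struct_b, chain_b)):
            for key, value in _structure_metrics(st, ch, config).items():
                result[f"{key}_{side}"] = value
    result["_record_a"] = record_a
    result["_record_b"] = record_b
    return result


DESCRIPTOR_KEYS = ("pI", "net_charge_pH7", "hydrophobic_pct",
                   "polar_pct", "nonpolar_pct")


def run_group_analysis(manifest: pd.DataFrame,
                       config: PipelineConfig = PipelineConfig(),
                       base_dir: Optional[Path] = None) -> ComparisonReport:
    """Run every manifest row and aggregate the group comparison."""
    results = []
    skipped = []
    for _, row in manifest.iterrows():
        try:
            results.append(run_pair(row, config, base_dir))
        except (ExstabError, OSError, ValueError) as exc:
            reason = f"{type(exc).__name__}: {exc}"
            logger.warning("row %s/%s skipped: %s",
                           row.get("id_a"), row.get("id_b"), reason)
            skipped.append({"id_a": row.get("id_a"), "id_b": row.get("id_b"),
                            "reason": reason})
    if not results:
        raise EmptyReportError("no manifest row could be processed")

    records_a = [r.pop("_record_a") for r in results]
    records_b = [r.pop("_record_b") for r in results]
    per_pair = pd.DataFrame(results)

    profiles_a = [composition.composition_percent(r) for r in records_a]
    profiles_b = [composition.composition_percent(r) for r in records_b]

    if len(profiles_a) >= 2 and len(profiles_b) >= 2:
        comp_tests = composition.compare_composition(
            profiles_a, profiles_b, variant=config.t_test_variant)
    else:
        comp_tests = pd.DataFrame(
            columns=["mean_a", "mean_b", "t", "df", "p"])

    desc_rows = []
    if len(per_pair) >= 2:
        for key in DESCRIPTOR_KEYS:
            res = stats.t_test(per_pair[f"{key}_a"], per_pair[f"{key}_b"],
                               variant=config.t_test_variant, parameter=key)
            desc_rows.append(asdict(res))
    descriptor_tests = pd.DataFrame(
        desc_rows, columns=["parameter", "mean_a", "mean_b", "t", "df", "p",
                            "infinite_t"])

    corr_records = stats.category_correlations(
        per_pair[per_pair["rmsd"].notna()]
        if "rmsd" in per_pair else per_pair.iloc[0:0])
    correlations = pd.DataFrame(
        [asdict(c) for c in corr_records], columns=["category", "n", "r"])

    occ_a = composition.bin_occurrences(profiles_a).counts if profiles_a else None
    occ_b = composition.bin_occurrences(profiles_b).counts if profiles_b else None

    return ComparisonReport(
        per_pair=per_pair,
        composition_tests=comp_tests,
        descriptor_tests=descriptor_tests,
        correlations=correlations,
        occurrence_a=occ_a,
        occurrence_b=occ_b,
        skipped=skipped,
    )
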
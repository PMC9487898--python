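"""End-to-end orchestration: annotate, analyze, aggregate, write tables.

The job is chunked by protein; within a chunk, per-structure analyses are
distributed over a flat worker pool with a determinism contract (outputs are
independent of worker count and chunk size).  Analyses are cached in memory
for the run and, outside lite mode, persisted to disk so that every structure
is analyzed exactly once across runs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from ..aggregation_classify import AggregatedPosition, aggregate_position, quality_score
from ..aggregation_classify.classify import classify_position
from ..aggregation_classify.evidence import render_residue_ref, render_structure_ref
from ..config import AnalysisConfig, DEFAULT_CONFIG
from ..registry import EVIDENCE_NAMES, FEATURE_NAMES
from ..residue_analysis.contacts import ResKey
from ..residue_analysis.features import StructureAnalysis, analyze_structure
from ..search_align import (
    SeqToStructAnnotation,
    TemplateLibrary,
    accept_annotation,
    align_global_free_end,
    alignment_coverage,
    find_candidates,
    map_positions,
)
from ..structures_io import extract_atom_sequence, parse_structure
from ..variants_indels import (
    aggregate_indel_features,
    apply_variant,
    decompose_indel,
    sav_feature_vector,
    span_positions,
    validate_variant,
)
from ..variants_indels.vectors import _aggregate_region
from .cache import AnalysisCache
from .inputs import Job, chunk_input
from .outputs import (
    write_classification_table,
    write_feature_manifest,
    write_feature_table,
    write_indel_feature_table,
    write_skipped_inputs,
    write_tag_summary,
)

logger = logging.getLogger("structannot")


@dataclass
class PipelineStats:
    structures_analyzed: int = 0
    cache_hits: int = 0
    n_chunks: int = 0
    n_annotations: int = 0
    runtime_s: float = 0.0


@dataclass
class PipelineResult:
    outdir: Path
    stats: PipelineStats
    classification_rows: list[dict] = field(default_factory=list)
    feature_rows: list[dict] = field(default_factory=list)
    indel_rows: list[dict] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class _Unit:
    """One sequence to annotate with the positions that must be aggregated."""

    unit_id: str
    sequence: str
    positions: set[int]
    annotations: list[SeqToStructAnnotation] = field(default_factory=list)
    aggregated: dict[int, AggregatedPosition] = field(default_factory=dict)


def build_annotations(
    query_id: str,
    sequence: str,
    library: TemplateLibrary,
    config: AnalysisConfig = DEFAULT_CONFIG,
    candidate_search=None,
) -> list[SeqToStructAnnotation]:
    """Candidate search + alignment + acceptance for one query sequence."""
    search = candidate_search or find_candidates
    annotations: list[SeqToStructAnnotation] = []
    for entry_id, chain_id in search(sequence, library.chain_sequences, config.kmer_size):
        template_seq = library.chain_sequences[(entry_id, chain_id)]
        aln = align_global_free_end(sequence, template_seq,
                                    config.gap_open, config.gap_extend)
        if not accept_annotation(aln.identity, config.identity_threshold,
                                 config.identity_inclusive):
            continue
        model = library.model(entry_id)
        _, template_keys = extract_atom_sequence(model, chain_id)
        position_map = map_positions(aln, template_keys)
        coverage = alignment_coverage(aln, position_map)
        annotation = SeqToStructAnnotation(
            query_id=query_id,
            entry_id=entry_id,
            chain_id=chain_id,
            alignment=aln,
            resolution=model.resolution,
            position_map=position_map,
            coverage=coverage,
            quality=quality_score(aln.identity, coverage, model.resolution),
            is_own_structure=aln.identity >= 0.99,
        )
        annotations.append(annotation)
    return annotations


def _analyze_entry_task(args) -> StructureAnalysis:
    path, entry_id, config, only_residues = args
    model = parse_structure(path, entry_id)
    return analyze_structure(model, config, only_residues)


def _pmap(items: list, workers: int) -> list[StructureAnalysis]:
    if workers <= 1 or len(items) < 2:
        return [_analyze_entry_task(item) for item in items]
    import multiprocessing

    ctx = multiprocessing.get_context("fork")
    with ctx.Pool(min(workers, len(items))) as pool:
        return pool.map(_analyze_entry_task, items)


def _resolve_sequence(protein_id: str, library: TemplateLibrary) -> str | None:
    """Sequence for a bare identifier from the template library (ENTRY or
    ENTRY:CHAIN)."""
    if ":" in protein_id:
        entry_id, _, chain_id = protein_id.partition(":")
        return library.chain_sequences.get((entry_id, chain_id))
    chains = [key for key in library.chain_sequences if key[0] == protein_id]
    if len(chains) == 1:
        return library.chain_sequences[chains[0]]
    return None


def _ss_label(features: dict | None) -> str | None:
    if features is None:
        return None
    triplet = {
        "Helix": features.get("ss_helix"),
        "Sheet": features.get("ss_sheet"),
        "Coil": features.get("ss_coil"),
    }
    defined = {k: v for k, v in triplet.items() if v is not None}
    if not defined:
        return None
    return max(defined, key=lambda k: (defined[k], k))


def _classification_row(
    input_id: str,
    primary_id: str,
    position_text: str,
    wt_residue: str,
    tags: list[str],
    agg: AggregatedPosition | None,
) -> dict:
    row = {
        "input_protein_id": input_id,
        "primary_protein_id": primary_id,
        "position": position_text,
        "wt_residue": wt_residue or None,
        "tags": ",".join(tags) if tags else None,
    }
    if agg is None or not agg.is_mapped:
        labels = (agg.labels if agg is not None
                  else classify_position(None))
        row.update({
            "structural_class": labels["structural_class"],
            "simple_class": labels["simple_class"],
            "rin_class": labels["rin_class"],
            "rin_simple_class": labels["rin_simple_class"],
            "n_mapped_structures": 0,
        })
        return row
    f = agg.features
    labels = agg.labels
    rec, rec_rf = agg.recommended_annotation, agg.recommended_residue
    mx, mx_rf = agg.max_identity_annotation, agg.max_identity_residue
    row.update({
        "weighted_location": labels["location"],
        "weighted_mainchain_location": labels["mainchain_location"],
        "weighted_sidechain_location": labels["sidechain_location"],
        "weighted_rsa": f.get("rsa_all"),
        "weighted_mainchain_rsa": f.get("rsa_mainchain"),
        "weighted_sidechain_rsa": f.get("rsa_sidechain"),
        "structural_class": labels["structural_class"],
        "simple_class": labels["simple_class"],
        "rin_class": labels["rin_class"],
        "rin_simple_class": labels["rin_simple_class"],
        "interaction_profile": labels["interaction_profile"],
        "weighted_secondary_structure": _ss_label(f),
        "classification_confidence": agg.confidence,
        "n_mapped_structures": agg.evidence.get("n_mapped_structures"),
        "recommended_structure_id": render_structure_ref(rec) if rec else None,
        "recommended_structure_residue": render_residue_ref(rec_rf),
        "recommended_identity": rec.identity if rec else None,
        "recommended_coverage": rec.coverage if rec else None,
        "recommended_resolution": rec.resolution if rec else None,
        "max_identity_structure_id": render_structure_ref(mx) if mx else None,
        "max_identity_structure_residue": render_residue_ref(mx_rf),
        "max_identity": mx.identity if mx else None,
        "max_identity_resolution": mx.resolution if mx else None,
    })
    return row


def _indel_classification_row(
    input_id: str,
    primary_id: str,
    variant,
    wt_positions: list[int],
    aggs: dict[int, AggregatedPosition],
) -> dict:
    """Classification row for an indel: region-aggregated features over the
    mapped WT flank/indel positions, evidence from their union."""
    region_features = _aggregate_region(wt_positions, aggs)
    mapped = [aggs[p] for p in wt_positions
              if p in aggs and aggs[p].is_mapped]
    if not mapped or all(v is None for v in region_features.values()):
        return _classification_row(input_id, primary_id, variant.text(),
                                   variant.wt_residues, variant.tags, None)
    labels = classify_position(region_features)
    representative = max(
        mapped, key=lambda a: ((a.confidence or 0.0), -a.position)
    )
    confidences = [a.confidence for a in mapped if a.confidence is not None]
    row = _classification_row(input_id, primary_id, variant.text(),
                              variant.wt_residues, variant.tags, representative)
    row.update({
        "weighted_location": labels["location"],
        "weighted_mainchain_location": labels["mainchain_location"],
        "weighted_sidechain_location": labels["sidechain_location"],
        "weighted_rsa": region_features.get("rsa_all"),
        "weighted_mainchain_rsa": region_features.get("rsa_mainchain"),
        "weighted_sidechain_rsa": region_features.get("rsa_sidechain"),
        "structural_class": labels["structural_class"],
        "simple_class": labels["simple_class"],
        "rin_class": labels["rin_class"],
        "rin_simple_class": labels["rin_simple_class"],
        "interaction_profile": labels["interaction_profile"],
        "weighted_secondary_structure": _ss_label(region_features),
        "classification_confidence": (sum(confidences) / len(confidences)
                                      if confidences else None),
    })
    return row


def run_pipeline(
    job: Job,
    template_dir: str | Path,
    outdir: str | Path,
    config: AnalysisConfig = DEFAULT_CONFIG,
    candidate_search=None,
    cache_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole annotation pipeline and write the output tables."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = TemplateLibrary(template_dir)
    stats = PipelineStats()
    result = PipelineResult(outdir=outdir, stats=stats)

    cache: AnalysisCache | None = None
    if not config.lite:
        cache = AnalysisCache(cache_dir or outdir / "cache", config)

    # ---- resolve sequences and deduplicate identical ones -----------------
    sequences: dict[str, str] = {}
    for pid, entry in job.proteins.items():
        seq = entry.sequence
        if seq is None:
            seq = _resolve_sequence(pid, library)
        if seq is None:
            result.skipped.append((pid, "no sequence available"))
            continue
        sequences[pid] = seq
    primary_of_seq: dict[str, str] = {}
    primary_id: dict[str, str] = {}
    for pid, seq in sequences.items():
        primary_of_seq.setdefault(seq, pid)
        primary_id[pid] = primary_of_seq[seq]

    # ---- build annotation units (WT per unique sequence, MUT per indel) ---
    wt_units: dict[str, _Unit] = {}  # primary id -> unit
    mut_units: dict[tuple[str, str], _Unit] = {}  # (primary id, variant text)
    valid_variants: dict[str, list] = {pid: [] for pid in sequences}
    for pid, entry in job.proteins.items():
        if pid not in sequences:
            continue
        seq = sequences[pid]
        prim = primary_id[pid]
        unit = wt_units.setdefault(prim, _Unit(prim, seq, set()))
        if entry.annotate_all:
            unit.positions.update(range(1, len(seq) + 1))
        for variant in entry.variants:
            try:
                validate_variant(variant, seq)
            except ValueError as exc:
                result.skipped.append((pid, f"variant {variant.text()}: {exc}"))
                continue
            valid_variants[pid].append(variant)
            if variant.kind == "sav":
                unit.positions.add(variant.left)
            else:
                mut_seq = apply_variant(seq, variant)
                dec = decompose_indel(seq, mut_seq, variant)
                for span in dec.wt_spans():
                    unit.positions.update(span_positions(span))
                mut_positions = set()
                for span in dec.mut_spans():
                    mut_positions.update(span_positions(span))
                key = (prim, variant.text())
                if key not in mut_units:
                    mut_units[key] = _Unit(f"{prim}|{variant.text()}", mut_seq,
                                           mut_positions)
                else:
                    mut_units[key].positions.update(mut_positions)

    # ---- process chunk by chunk ------------------------------------------
    memory_cache: dict[str, StructureAnalysis] = {}
    chunk_ids = chunk_input(job, config.chunk_size)
    stats.n_chunks = len(chunk_ids)
    done_units: set[str] = set()
    for chunk in chunk_ids:
        units: list[_Unit] = []
        for pid in chunk:
            if pid not in sequences:
                continue
            prim = primary_id[pid]
            if prim in done_units:
                continue
            done_units.add(prim)
            units.append(wt_units[prim])
            for (uprim, vtext), unit in mut_units.items():
                if uprim == prim:
                    units.append(unit)
        if not units:
            continue

        for unit in units:
            unit.annotations = build_annotations(unit.unit_id, unit.sequence,
                                                 library, config, candidate_search)
            stats.n_annotations += len(unit.annotations)

        # which residues of which entries are needed
        needed: dict[str, set[ResKey]] = {}
        for unit in units:
            for ann in unit.annotations:
                keys = needed.setdefault(ann.entry_id, set())
                for pos in unit.positions:
                    mapped = ann.position_map.get(pos)
                    if mapped is not None:
                        keys.add((ann.chain_id,) + mapped)

        to_compute: list[tuple] = []
        for entry_id in sorted(needed):
            if entry_id in memory_cache:
                # a lite-mode analysis may not cover newly needed residues
                if config.lite and needed[entry_id] - set(memory_cache[entry_id].residues):
                    prev = set(memory_cache.pop(entry_id).residues)
                    needed[entry_id] |= prev
                else:
                    continue
            if cache is not None:
                loaded = cache.load(entry_id)
                if loaded is not None:
                    memory_cache[entry_id] = loaded
                    stats.cache_hits += 1
                    continue
            only = needed[entry_id] if config.lite else None
            to_compute.append((library.path(entry_id), entry_id, config, only))

        if to_compute:
            logger.info("analyzing %d structures", len(to_compute))
            for analysis in _pmap(to_compute, config.workers):
                memory_cache[analysis.entry_id] = analysis
                stats.structures_analyzed += 1
                if cache is not None:
                    cache.store(analysis)

        # aggregate every needed position of every unit in this chunk
        for unit in units:
            for pos in sorted(unit.positions):
                features = []
                for ann in unit.annotations:
                    mapped = ann.position_map.get(pos)
                    rf = None
                    if mapped is not None:
                        analysis = memory_cache.get(ann.entry_id)
                        if analysis is not None:
                            rf = analysis.get((ann.chain_id,) + mapped)
                    features.append(rf)
                unit.aggregated[pos] = aggregate_position(
                    unit.unit_id, pos, unit.annotations, features, config)

    # ---- assemble output rows in input order ------------------------------
    for pid, entry in job.proteins.items():
        if pid not in sequences:
            continue
        seq = sequences[pid]
        prim = primary_id[pid]
        unit = wt_units[prim]
        if entry.annotate_all:
            for pos in range(1, len(seq) + 1):
                agg = unit.aggregated.get(pos)
                text = f"{seq[pos - 1]}{pos}"
                result.classification_rows.append(_classification_row(
                    pid, prim, text, seq[pos - 1], [], agg))
                result.feature_rows.append({
                    "protein_id": pid, "position": text, "tags": None,
                    **sav_feature_vector(agg),
                })
        for variant in valid_variants[pid]:
            if variant.kind == "sav":
                agg = unit.aggregated.get(variant.left)
                result.classification_rows.append(_classification_row(
                    pid, prim, variant.text(), variant.wt_residues,
                    variant.tags, agg))
                result.feature_rows.append({
                    "protein_id": pid, "position": variant.text(),
                    "tags": ",".join(variant.tags) if variant.tags else None,
                    **sav_feature_vector(agg),
                })
            else:
                mut_unit = mut_units[(prim, variant.text())]
                mut_seq = mut_unit.sequence
                dec = decompose_indel(seq, mut_seq, variant)
                wt_positions = [p for span in dec.wt_spans()
                                for p in span_positions(span)]
                result.classification_rows.append(_indel_classification_row(
                    pid, prim, variant, wt_positions, unit.aggregated))
                vector = aggregate_indel_features(unit.aggregated,
                                                  mut_unit.aggregated, dec)
                result.indel_rows.append({
                    "protein_id": pid, "position": variant.text(),
                    "tags": ",".join(variant.tags) if variant.tags else None,
                    **vector,
                })

    # ---- write tables -----------------------------------------------------
    write_classification_table(result.classification_rows, outdir)
    write_feature_table(result.feature_rows, outdir)
    write_indel_feature_table(result.indel_rows, outdir)
    write_feature_manifest(outdir)
    write_tag_summary(result.classification_rows, outdir)
    write_skipped_inputs(result.skipped, outdir)
    stats.runtime_s = time.time() - t0
    (outdir / "run.log").write_text(
        "structures_analyzed\t{}\ncache_hits\t{}\nchunks\t{}\nannotations\t{}\n"
        "runtime_s\t{:.3f}\n".format(stats.structures_analyzed, stats.cache_hits,
                                     stats.n_chunks, stats.n_annotations,
                                     stats.runtime_s))
    return result
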
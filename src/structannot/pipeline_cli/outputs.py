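"""TSV output writers: classification table, feature tables, manifest,
tag summary and skipped-inputs report."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..registry import INDEL_VECTOR_NAMES, SAV_VECTOR_NAMES

UNDEF = "-"

CLASSIFICATION_COLUMNS = (
    "input_protein_id",
    "primary_protein_id",
    "position",
    "wt_residue",
    "tags",
    "weighted_location",
    "weighted_mainchain_location",
    "weighted_sidechain_location",
    "weighted_rsa",
    "weighted_mainchain_rsa",
    "weighted_sidechain_rsa",
    "structural_class",
    "simple_class",
    "rin_class",
    "rin_simple_class",
    "interaction_profile",
    "weighted_secondary_structure",
    "classification_confidence",
    "n_mapped_structures",
    "recommended_structure_id",
    "recommended_structure_residue",
    "recommended_identity",
    "recommended_coverage",
    "recommended_resolution",
    "max_identity_structure_id",
    "max_identity_structure_residue",
    "max_identity",
    "max_identity_resolution",
)

FEATURE_KEY_COLUMNS = ("protein_id", "position", "tags")


def fmt_value(value) -> str:
    """Stable text rendering: undefined -> '-', floats at 6 significant digits."""
    if value is None:
        return UNDEF
    if isinstance(value, str):
        return value if value else UNDEF
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if float(value).is_integer():
            return str(int(value))
        return format(float(value), ".6g")
    return str(value)


def _write_table(path: Path, header: tuple[str, ...], rows: list[dict]) -> Path:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(fmt_value(row.get(col)) for col in header))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_classification_table(rows: list[dict], outdir: Path) -> Path:
    return _write_table(outdir / "classification.tsv", CLASSIFICATION_COLUMNS, rows)


def write_feature_table(rows: list[dict], outdir: Path) -> Path:
    header = FEATURE_KEY_COLUMNS + SAV_VECTOR_NAMES
    return _write_table(outdir / "features.tsv", header, rows)


def write_indel_feature_table(rows: list[dict], outdir: Path) -> Path:
    header = FEATURE_KEY_COLUMNS + INDEL_VECTOR_NAMES
    return _write_table(outdir / "indel_features.tsv", header, rows)


def write_feature_manifest(outdir: Path) -> Path:
    lines = ["table\tcolumn_index\tfeature_name"]
    for i, name in enumerate(SAV_VECTOR_NAMES, 1):
        lines.append(f"features\t{i}\t{name}")
    for i, name in enumerate(INDEL_VECTOR_NAMES, 1):
        lines.append(f"indel_features\t{i}\t{name}")
    path = outdir / "feature_manifest.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


def write_tag_summary(classification_rows: list[dict], outdir: Path) -> Path:
    """Per-tag position counts by simple class and RSA mean/median."""
    by_tag: dict[str, list[dict]] = {}
    for row in classification_rows:
        tags = row.get("tags") or ""
        for tag in tags.split(","):
            tag = tag.strip()
            if tag:
                by_tag.setdefault(tag, []).append(row)
    header = ("tag", "n_positions", "n_core", "n_surface", "n_interaction",
              "n_no_structure", "mean_rsa", "median_rsa")
    rows = []
    for tag in sorted(by_tag):
        group = by_tag[tag]
        classes = [r.get("simple_class") for r in group]
        rsas = [r.get("weighted_rsa") for r in group if isinstance(r.get("weighted_rsa"), float)]
        rows.append({
            "tag": tag,
            "n_positions": len(group),
            "n_core": classes.count("Core"),
            "n_surface": classes.count("Surface"),
            "n_interaction": classes.count("Interaction"),
            "n_no_structure": classes.count("No structure"),
            "mean_rsa": float(np.mean(rsas)) if rsas else None,
            "median_rsa": float(np.median(rsas)) if rsas else None,
        })
    return _write_table(outdir / "tag_summary.tsv", header, rows)


def write_skipped_inputs(skipped: list[tuple[str, str]], outdir: Path) -> Path:
    lines = ["protein_id\treason"]
    lines += [f"{pid}\t{reason}" for pid, reason in skipped]
    path = outdir / "skipped_inputs.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path
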
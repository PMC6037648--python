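"""End-to-end orchestration: simulate -> detect -> classify -> logo -> tree.

Stages hand off through flat files (TSV/JSON/Newick) so each one is
independently testable and scriptable; every output file embeds the run seed
and a hash of the configuration in a header comment line.  The default
profile source is "synthetic-trained": per-group CSR profiles trained on the
truth fingerprints of a generated dataset.  For real sequence collections a
curated profile JSON should be supplied instead.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import classify as _classify
from . import detect as _detect
from . import logo as _logo
from . import phylo as _phylo
from .schema import ENZYME, GroupCatalogue, default_catalogue, default_rules, default_schema
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset

log = logging.getLogger("gh57")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings shared by the pipeline stages."""

    seed: int = 1602
    floor_fraction: float = 0.15
    min_spacer: int = 5
    assign_threshold: float = 0.0
    bootstrap_trials: int = 1000
    max_tree_leaves: int = 200
    pseudocount: float = 0.5


def config_hash(obj) -> str:
    """Short stable hash of a configuration object (dataclass or mapping)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_comment(seed: int, cfg_hash: str) -> str:
    return f"seed={seed} config_hash={cfg_hash}"


def train_profile_sets(
    dataset: SyntheticDataset,
    pseudocount: float = 0.5,
    catalogue: GroupCatalogue | None = None,
) -> dict[str, _detect.ProfileSet]:
    """One profile set per group, trained on its truth fingerprints.

    Detection scans with all of these (like-protein groups included, so their
    diverged CSRs are found); classification scores the enzyme-group subset
    only (see :func:`enzyme_profile_sets`) with like labels decided by the
    catalytic machinery.
    """
    by_group: dict[str, list[str]] = {}
    for seq in dataset.non_decoys:
        by_group.setdefault(seq.group, []).append(seq.fingerprint)
    return {
        group: _detect.profiles_from_alignment(
            fps, pseudocount=pseudocount, schema=dataset.schema, name=group
        )
        for group, fps in by_group.items()
    }


def enzyme_profile_sets(
    profile_sets: Mapping[str, _detect.ProfileSet],
    catalogue: GroupCatalogue | None = None,
) -> dict[str, _detect.ProfileSet]:
    """Restrict a profile-set mapping to the enzyme specificity groups."""
    catalogue = catalogue or default_catalogue()
    return {
        g: p for g, p in profile_sets.items() if g in catalogue and catalogue[g].kind == ENZYME
    }


def builtin_profile_sets(seed: int = 1602, pseudocount: float = 0.5) -> dict[str, _detect.ProfileSet]:
    """Synthetic-trained default profiles (deterministic in ``seed``)."""
    dataset = generate_dataset(SyntheticConfig(seed=seed, dropout_fraction=0.0))
    return train_profile_sets(dataset, pseudocount=pseudocount)


def read_fasta(path) -> list[tuple[str, str]]:
    try:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    except OSError as exc:
        raise OSError(f"cannot read FASTA {path}: {exc}") from exc


@dataclass
class AnalysisResult:
    fingerprints: pd.DataFrame
    assignments: pd.DataFrame
    summary: _classify.SummaryReport
    logos: list[_logo.LogoMatrix]
    tree: object | None  # skbio TreeNode
    tree_leaves: list[str]
    assignment_objects: list[_classify.GroupAssignment] = field(default_factory=list)


def detect_records(
    records: Sequence[tuple[str, str]],
    profile_sets: Mapping[str, _detect.ProfileSet],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Scan every record against all profile sets; tabulate hits/eliminations."""
    rows = []
    sets = list(profile_sets.values())
    for seq_id, sequence in records:
        hits = _detect.scan_sequence(
            sequence, sets, min_spacer=config.min_spacer, floor_fraction=config.floor_fraction
        )
        row: dict = {
            "id": seq_id,
            "status": "accepted" if hits.accepted else "eliminated",
            "reason": hits.reason or "",
            "profile": hits.profile_name or "",
            "total_score": round(hits.total_score, 4) if hits.total_score is not None else "",
        }
        for k in range(5):
            if hits.ranges is not None:
                row[f"csr{k + 1}_start"], row[f"csr{k + 1}_end"] = hits.ranges[k]
                row[f"csr{k + 1}_score"] = round(hits.csr_scores[k], 4)
            else:
                row[f"csr{k + 1}_start"] = row[f"csr{k + 1}_end"] = row[f"csr{k + 1}_score"] = ""
        row["fingerprint"] = (
            _detect.extract_fingerprint(sequence, hits) if hits.accepted else ""
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _stratified_subsample(
    labels: Mapping[str, str], max_leaves: int, rng: np.random.Generator
) -> list[str]:
    """At most ``max_leaves`` ids, proportional per label with >= 1 each."""
    by_label: dict[str, list[str]] = {}
    for seq_id, label in labels.items():
        by_label.setdefault(label, []).append(seq_id)
    total = len(labels)
    if total <= max_leaves:
        return list(labels)
    chosen: list[str] = []
    groups = sorted(by_label)
    quotas = {}
    for g in groups:
        quotas[g] = max(1, int(round(max_leaves * len(by_label[g]) / total)))
    while sum(quotas.values()) > max_leaves:
        biggest = max(groups, key=lambda g: (quotas[g], g))
        if quotas[biggest] <= 1:
            break
        quotas[biggest] -= 1
    for g in groups:
        members = sorted(by_label[g])
        take = min(quotas[g], len(members))
        idx = rng.choice(len(members), size=take, replace=False)
        chosen.extend(members[i] for i in sorted(idx))
    return chosen


def analyze_records(
    records: Sequence[tuple[str, str]],
    profile_sets: Mapping[str, _detect.ProfileSet],
    config: PipelineConfig | None = None,
    *,
    catalogue: GroupCatalogue | None = None,
    taxonomy: Mapping[str, str] | None = None,
) -> AnalysisResult:
    """Run detection, classification, logos and the bootstrapped tree."""
    config = config or PipelineConfig()
    catalogue = catalogue or default_catalogue()
    rules = default_rules()
    schema = default_schema()

    fp_table = detect_records(records, profile_sets, config)
    accepted = fp_table[fp_table["status"] == "accepted"]
    n_elim = int((fp_table["status"] == "eliminated").sum())
    log.info("detect: %d read, %d accepted, %d eliminated", len(fp_table), len(accepted), n_elim)

    scoring_sets = enzyme_profile_sets(profile_sets, catalogue) or dict(profile_sets)
    assignments = [
        _classify.classify_fingerprint(
            row.id, row.fingerprint, scoring_sets,
            catalogue=catalogue, rules=rules, schema=schema,
            threshold=config.assign_threshold,
        )
        for row in accepted.itertuples()
    ]
    assign_table = _classify.assignments_frame(assignments)
    summary = _classify.summarize(
        assignments, taxonomy, eliminated=n_elim, catalogue=catalogue
    )
    log.info(
        "classify: %d classified, %d unclassified", summary.classified, summary.unclassified
    )

    by_label: dict[str, list[str]] = {}
    fp_of: dict[str, str] = {}
    for a, row in zip(assignments, accepted.itertuples()):
        fp_of[a.seq_id] = row.fingerprint
        if a.label != _classify.UNCLASSIFIED:
            by_label.setdefault(a.label, []).append(a.seq_id)
    logos = [
        _logo.logo_from_fingerprints([fp_of[i] for i in ids], group=label, schema=schema)
        for label, ids in sorted(by_label.items())
    ]

    tree = None
    leaves: list[str] = []
    labels = {i: label for label, ids in by_label.items() for i in ids}
    if len(labels) >= 3:
        rng = np.random.default_rng(config.seed)
        leaves = _stratified_subsample(labels, config.max_tree_leaves, rng)
        tree = _phylo.bootstrap_support(
            [fp_of[i] for i in leaves], leaves,
            n_trials=config.bootstrap_trials, seed=config.seed,
        )
        log.info("tree: %d leaves, %d bootstrap trials", len(leaves), config.bootstrap_trials)

    return AnalysisResult(
        fingerprints=fp_table,
        assignments=assign_table,
        summary=summary,
        logos=logos,
        tree=tree,
        tree_leaves=leaves,
        assignment_objects=assignments,
    )


def _write_tsv(df: pd.DataFrame, path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_simulate(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Generate a dataset and write FASTA + truth TSV + manifest."""
    os.makedirs(outdir, exist_ok=True)
    dataset = generate_dataset(config)
    chash = config_hash(config)
    comment = header_comment(config.seed, chash)
    fasta = os.path.join(outdir, "synthetic.fasta")
    truth = os.path.join(outdir, "truth.tsv")
    manifest = os.path.join(outdir, "manifest.json")
    dataset.write_fasta(fasta)
    dataset.write_truth(truth, header_comment=comment)
    with open(manifest, "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "config_hash": chash,
                "n_sequences": len(dataset),
                "n_decoys": sum(s.decoy for s in dataset.sequences),
                "config": dataclasses.asdict(config),
            },
            fh,
            indent=2,
            default=str,
        )
        fh.write("\n")
    log.info("simulate: wrote %d sequences to %s", len(dataset), fasta)
    return {"fasta": fasta, "truth": truth, "manifest": manifest}


def run_analyze(
    fasta_path,
    outdir,
    config: PipelineConfig | None = None,
    profile_sets: Mapping[str, _detect.ProfileSet] | None = None,
    taxonomy: Mapping[str, str] | None = None,
) -> AnalysisResult:
    """Full pipeline on a FASTA file; writes all stage outputs to ``outdir``."""
    config = config or PipelineConfig()
    os.makedirs(outdir, exist_ok=True)
    records = read_fasta(fasta_path)
    if profile_sets is None:
        profile_sets = builtin_profile_sets(config.seed, pseudocount=config.pseudocount)
    result = analyze_records(records, profile_sets, config, taxonomy=taxonomy)

    chash = config_hash(config)
    comment = header_comment(config.seed, chash)
    _write_tsv(result.fingerprints, os.path.join(outdir, "fingerprints.tsv"), comment)
    _write_tsv(result.assignments, os.path.join(outdir, "assignments.tsv"), comment)
    summary_df = result.summary.per_group.copy()
    _write_tsv(summary_df, os.path.join(outdir, "summary.tsv"), comment)
    with open(os.path.join(outdir, "logos.json"), "w") as fh:
        json.dump(
            {"seed": config.seed, "config_hash": chash,
             "logos": [lg.to_jsonable() for lg in result.logos]},
            fh,
        )
        fh.write("\n")
    if result.tree is not None:
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(f"[{comment}]\n")
            fh.write(str(result.tree).strip() + "\n")
        label_of = dict(zip(result.assignments["id"], result.assignments["label"]))
        annot = pd.DataFrame(
            {
                "leaf": result.tree_leaves,
                "label": [label_of.get(i, "") for i in result.tree_leaves],
                "taxonomy": [(taxonomy or {}).get(i, "") for i in result.tree_leaves],
            }
        )
        _write_tsv(annot, os.path.join(outdir, "tree_annotation.tsv"), comment)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "config_hash": chash,
                "n_input": len(records),
                "n_eliminated": int(result.summary.eliminated),
                "n_classified": int(result.summary.classified),
                "n_unclassified": int(result.summary.unclassified),
                "tree_leaves": len(result.tree_leaves),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return result
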
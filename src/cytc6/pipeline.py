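"""End-to-end workflows: classify, map, simulate.

Each workflow is a plain function over a :class:`RunConfig` (YAML-loadable)
so that the command-line layer stays thin and everything is callable — and
deterministic — from library code and tests. Results go to files; logs go
to the logging subsystem (stderr under the CLI). Every configured default
is echoed into the log at run start, and every input record is accounted
for at run end: input count = classified + unclassified + filtered.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import distribution
from .classify import (
    C6,
    C6A,
    C6B,
    UNCLASSIFIED,
    ClassRule,
    LipSpec,
    assign_class,
    extract_features,
)
from .preprocess import (
    FilterConfig,
    UntrimmableError,
    find_haem_motif,
    length_filter,
    trim_signal_peptide,
)
from .reference_align import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    DEFAULT_MATRIX,
    ReferenceProfile,
)
from .sequence_io import read_clade_map, read_fasta, write_clade_map, write_fasta
from .synthetic_data import ScenarioConfig, Scenario, simulate_scenario

log = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "id", "taxon", "label", "reason", "motif_position", "diagnostic_residue",
    "lip_length", "lip_cys_count", "trim_offset", "score_c6a", "score_c6", "flags",
]


class ReferenceError(ValueError):
    """Missing or unusable reference sequences."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a classification run (flat, YAML-serializable)."""

    fasta: str = ""
    references: str = ""
    newick: str = ""
    clade_map: str = ""
    out_dir: str = "cytc6_out"
    seed: int = 0
    min_len: int = 80
    max_len: int = 200
    motif_window: tuple[int, int] = (5, 40)
    post_trim_min_len: int = 60
    lip_min_len: int = 8
    lip_max_len: int = 20
    lip_min_cys: int = 2
    diagnostic_position: int = 52
    loop_window: tuple[int, int] = (35, 50)
    matrix: str = DEFAULT_MATRIX
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        for key in ("motif_window", "loop_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_len=self.min_len,
            max_len=self.max_len,
            motif_window=self.motif_window,
            post_trim_min_len=self.post_trim_min_len,
        )

    def lip_spec(self) -> LipSpec:
        return LipSpec(self.lip_min_len, self.lip_max_len, self.lip_min_cys)


def load_references(path: str | Path) -> ReferenceProfile:
    """Load a two-sequence reference FASTA (ids ``ref_c6a`` and ``ref_c6``).

    The canonical accessions (A. thaliana Q93VA3.1 mature c6A and
    Synechococcus sp. PCC 7002 O30881.1 mature c6) are not bundled; fetch
    them with ``scripts/fetch_references.py`` or use a bundle written by
    ``cytc6 simulate``.
    """
    try:
        records = {r.id: r for r in read_fasta(path)}
    except FileNotFoundError as exc:
        raise ReferenceError(
            f"reference FASTA {path!s} not found. Provide a FASTA with entries "
            "'ref_c6a' (mature plant-type c6A) and 'ref_c6' (mature "
            "cyanobacterial c6); see scripts/fetch_references.py to retrieve "
            "the canonical accessions, or use the references.fasta written by "
            "'cytc6 simulate'."
        ) from exc
    for required in ("ref_c6a", "ref_c6"):
        if required not in records:
            raise ReferenceError(
                f"reference FASTA {path!s} lacks entry {required!r} "
                "(expected ids: ref_c6a, ref_c6)"
            )
    return ReferenceProfile(c6a=records["ref_c6a"], c6=records["ref_c6"])


@dataclass
class ClassifyResult:
    report: pd.DataFrame
    filtered: pd.DataFrame
    out_dir: Path


def _log_config(cfg: RunConfig) -> None:
    for f in dataclasses.fields(cfg):
        log.info("config %s = %r", f.name, getattr(cfg, f.name))


def run_classify(cfg: RunConfig) -> ClassifyResult:
    """Preprocess → align → classify; write TSV/JSON reports.

    Every filtered sequence is logged with its reason and listed in
    ``filtered.tsv``; the classification report has one row per surviving
    record. Reruns with identical config and inputs are byte-identical.
    """
    logging.basicConfig(level=cfg.log_level)
    _log_config(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_fasta(cfg.fasta)
    refs = load_references(cfg.references)
    filter_cfg = cfg.filter_config()
    lip_spec = cfg.lip_spec()
    rule = ClassRule()

    rows: list[dict[str, Any]] = []
    dropped: list[dict[str, str]] = []
    traces: list[dict[str, Any]] = []
    for rec in records:
        res = length_filter(rec, filter_cfg)
        if not res.passed:
            log.info("filtered %s: %s", rec.id, res.reason)
            dropped.append({"id": rec.id, "stage": "length_filter", "reason": res.reason})
            continue
        try:
            matured = trim_signal_peptide(
                rec, refs, cfg.matrix, cfg.gap_open, cfg.gap_extend
            )
        except UntrimmableError as exc:
            log.info("filtered %s: UNTRIMMABLE", rec.id)
            dropped.append({"id": rec.id, "stage": "trim", "reason": f"UNTRIMMABLE: {exc}"})
            continue
        if len(matured.residues) < filter_cfg.post_trim_min_len:
            reason = (
                f"post-trim length {len(matured.residues)} below "
                f"{filter_cfg.post_trim_min_len}"
            )
            log.info("filtered %s: %s", rec.id, reason)
            dropped.append({"id": rec.id, "stage": "post_trim_length", "reason": reason})
            continue
        features = extract_features(
            matured, refs, lip_spec, filter_cfg,
            cfg.matrix, cfg.gap_open, cfg.gap_extend,
        )
        label = assign_class(features, rule)
        rows.append({
            "id": rec.id,
            "taxon": rec.taxon,
            "label": label.label,
            "reason": label.reason,
            "motif_position": features.motif_position if features.motif_position else "",
            "diagnostic_residue": features.diagnostic_residue,
            "lip_length": features.lip.length if features.lip else 0,
            "lip_cys_count": features.lip_cys_count,
            "trim_offset": matured.trim_offset,
            "score_c6a": features.alignment_scores["c6a"],
            "score_c6": features.alignment_scores["c6"],
            "flags": ";".join(label.flags),
        })
        traces.append({
            "id": rec.id,
            "label": label.label,
            "reason": label.reason,
            "flags": list(label.flags),
            "motif_position": features.motif_position,
            "diagnostic_residue": features.diagnostic_residue,
            "lip": dataclasses.asdict(features.lip) if features.lip else None,
            "low_cys_insertion": features.low_cys_insertion,
            "alignment_scores": dict(features.alignment_scores),
            "trim_offset": matured.trim_offset,
        })

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    filtered = pd.DataFrame(dropped, columns=["id", "stage", "reason"])
    n_unclassified = int((report["label"] == UNCLASSIFIED).sum()) if len(report) else 0
    assert len(records) == len(report) + len(filtered), "record accounting failed"
    log.info(
        "classified %d records (%d unclassified), filtered %d of %d input",
        len(report), n_unclassified, len(filtered), len(records),
    )
    report.to_csv(out_dir / "classification.tsv", sep="\t", index=False)
    filtered.to_csv(out_dir / "filtered.tsv", sep="\t", index=False)
    (out_dir / "classification.json").write_text(
        json.dumps(traces, indent=2, sort_keys=True) + "\n"
    )
    return ClassifyResult(report=report, filtered=filtered, out_dir=out_dir)


@dataclass
class MapResult:
    matrix: pd.DataFrame
    unclassified: pd.Series
    summary: pd.DataFrame
    reconstructions: list[distribution.EventReconstruction]
    out_dir: Path


def run_map(
    report: str | Path | pd.DataFrame,
    newick: str | Path,
    clade_map_path: str | Path | None = None,
    out_dir: str | Path = "cytc6_out",
) -> MapResult:
    """Aggregate labels, summarize per clade, and reconstruct events.

    Taxa present in the report but absent from the tree are listed with a
    warning and excluded from reconstruction (the run continues); tree
    leaves without any classified sequence count as absent.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(report, pd.DataFrame):
        report = pd.read_csv(report, sep="\t", keep_default_na=False)
    matrix, unclassified = distribution.build_presence_matrix(
        report[["id", "taxon", "label"]]
    )
    clade_map: Mapping[str, str] = (
        read_clade_map(clade_map_path) if clade_map_path else {}
    )
    summary = distribution.summarize_by_clade(matrix, clade_map)

    tree = distribution.read_newick(newick)
    tree_taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    extra = sorted(set(matrix.index) - tree_taxa)
    if extra:
        log.warning("taxa in report but not in tree (ignored): %s", ", ".join(extra))
    on_tree = matrix.loc[[t for t in matrix.index if t in tree_taxa]]

    c6_presence = {t: 0 for t in tree_taxa}
    states = {t: distribution.STATE_NONE for t in tree_taxa}
    derived, flagged = distribution.transition_states(on_tree)
    for t in on_tree.index:
        c6_presence[t] = int(on_tree.loc[t, C6] > 0)
        states[t] = derived[t]
    if flagged:
        log.warning("taxa carrying both C6A and C6B (treated as C6A): %s",
                    ", ".join(flagged))

    recs = [
        distribution.dollo_reconstruct(tree, c6_presence, family=C6),
        distribution.reconstruct_c6a_transition(tree, states),
    ]

    matrix.to_csv(out_dir / "presence_matrix.tsv", sep="\t")
    unclassified.to_csv(out_dir / "unclassified_counts.tsv", sep="\t", header=True)
    summary.to_csv(out_dir / "clade_summary.tsv", sep="\t")
    (out_dir / "clade_summary.md").write_text(
        distribution.summary_to_markdown(summary)
    )
    distribution.events_to_frame(recs).to_csv(
        out_dir / "events.tsv", sep="\t", index=False
    )
    (out_dir / "annotated_tree.nwk").write_text(
        distribution.annotated_newick(tree, recs) + "\n"
    )
    return MapResult(
        matrix=matrix,
        unclassified=unclassified,
        summary=summary,
        reconstructions=recs,
        out_dir=out_dir,
    )


def run_simulate(cfg: ScenarioConfig, out_dir: str | Path) -> Scenario:
    """Write a synthetic dataset bundle a classify+map run can consume.

    Bundle contents: ``sequences.fasta``, ``references.fasta``,
    ``tree.nwk``, ``clade_map.tsv``, ``truth.json`` (events, presence,
    per-sequence ground truth) and ``manifest.json`` (seed + config hash).
    Identical configs give byte-identical bundles.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario = simulate_scenario(cfg)
    write_fasta(scenario.sequences, out_dir / "sequences.fasta")
    write_fasta(
        [scenario.generator.profile.c6a, scenario.generator.profile.c6],
        out_dir / "references.fasta",
    )
    (out_dir / "tree.nwk").write_text(scenario.newick + "\n")
    write_clade_map(scenario.clade_map, out_dir / "clade_map.tsv")
    truth = {
        "events": [dataclasses.asdict(e) for e in scenario.events],
        "insertion_branch": scenario.insertion_branch,
        "presence": {
            taxon: {g: int(v) for g, v in row.items()}
            for taxon, row in scenario.presence.iterrows()
        },
        "sequences": {
            rid: dataclasses.asdict(t) for rid, t in scenario.truths.items()
        },
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    cfg_dict = dataclasses.asdict(cfg)
    if cfg.generator is not None:
        cfg_dict["generator"] = dataclasses.asdict(cfg.generator)
    canonical = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return scenario
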
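"""Pipeline orchestration: from sequences + alignment to subgroup report.

Stage order: domain splitting → redundancy filtering → substitution-matrix
distances → classical MDS → cluster-number selection with a randomization
null → cluster naming → per-cluster profile search of a family database →
conserved blocks → discriminating sites → reference numbering.  Every table
the summary reports is also written as its own TSV, so each number is
recomputable from the emitted stage outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import blocks_logos, clustering, distance_mds, profile_search, redundancy_filter
from .sequence_io import (
    Alignment,
    NotGenuineChimera,
    load_matrix,
    read_alignment,
    read_domain_spans,
    read_fasta,
    read_substitution_matrix,
    split_domains,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    fasta: str
    alignment: str
    spans: str
    matrix: str = "BLOSUM30"  # path to an NCBI-format file, or a bundled name
    alignment_format: str = "fasta"
    family_db: str | None = None
    family_map: str | None = None
    phylum_map: str | None = None
    references: dict[str, str] = field(default_factory=dict)  # seq_id -> name
    reference_priority: list[str] = field(default_factory=list)
    reference_id: str | None = None  # row used for site numbering
    reference_offset: int = 1
    identity_threshold: float = 0.5
    mds_components: int = 3
    k_min: int = 2
    k_max: int = 10
    e_threshold: float = 0.1
    max_gap_frac: float = 0.9
    min_block_len: int = 3
    jsd_threshold: float = 0.5
    null_replicates: int = 3
    restarts: int = 25
    seed: int = clustering.DEFAULT_SEED
    realign: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def contingency_table(
    assignments: dict[str, str], phylum: dict[str, str]
) -> pd.DataFrame:
    """Phylum × cluster counts with row/column totals.

    Ids without a phylum label are counted under "unknown".
    """
    rows = [
        {"phylum": phylum.get(sid, "unknown"), "cluster": cl}
        for sid, cl in assignments.items()
    ]
    if not rows:
        raise ValueError("no assignments")
    df = pd.DataFrame(rows)
    table = pd.crosstab(df["phylum"], df["cluster"], margins=True, margins_name="Total")
    table.index.name = "phylum"
    return table


def _load_matrix(spec: str):
    if Path(spec).exists():
        return read_substitution_matrix(spec)
    return load_matrix(spec)


def _read_map_tsv(path: str | Path, value_col: int = 1) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("seq_id", "id"):
                continue
            out[parts[0]] = parts[value_col]
    return out


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full analysis; returns the summary dict (also written to disk).

    On any stage failure the partially written outputs are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    stage = "setup"
    try:
        if cfg.realign:
            raise ValueError(
                "--realign is declared but not implemented: supply a "
                "precomputed master alignment via the 'alignment' input"
            )
        summary: dict[str, Any] = {"seed": cfg.seed, "config": cfg.echo()}
        matrix = _load_matrix(cfg.matrix)

        stage = "split_domains"
        records = read_fasta(cfg.fasta)
        spans = read_domain_spans(cfg.spans)
        aat_domains = []
        rejected = 0
        for rec in records:
            try:
                _, aat = split_domains(rec, spans)
            except NotGenuineChimera:
                rejected += 1
                continue
            aat_domains.append(aat)
        summary["counts"] = {"input": len(records), "rejected": rejected}
        logger.info("split_domains: %d input, %d rejected", len(records), rejected)

        stage = "redundancy_filter"
        red = redundancy_filter.greedy_cluster(
            aat_domains, threshold=cfg.identity_threshold, seed=cfg.seed
        )
        summary["counts"]["filtered"] = len(red.representatives)
        with open(emit("membership.tsv"), "w") as fh:
            fh.write("seq_id\trepresentative\n")
            for sid, rep in sorted(red.membership.items()):
                fh.write(f"{sid}\t{rep}\n")

        stage = "alignment"
        master = read_alignment(cfg.alignment, cfg.alignment_format)
        keep = set(red.representatives) | set(cfg.references)
        if cfg.reference_id:
            keep.add(cfg.reference_id)
        used_ids = [i for i in master.ids if i in keep]
        if len(used_ids) < 2:
            raise ValueError("fewer than two representative rows in the alignment")
        aln = master.subset(used_ids)
        # clustered may exceed filtered: reference rows are added post-filter
        summary["counts"]["clustered"] = len(used_ids)

        stage = "score_distance_matrix"
        dist = distance_mds.score_distance_matrix(aln, matrix)
        distance_mds.write_distance_tsv(dist, emit("distance.tsv"))

        stage = "classical_mds"
        proj = distance_mds.classical_mds(dist)
        distance_mds.write_coords_tsv(proj, emit("coords.tsv"))
        pd.DataFrame({"eigenvalue": proj.eigenvalues}).to_csv(
            emit("eigenvalues.tsv"), sep="\t", index=False
        )
        coords = proj.coords[:, : min(cfg.mds_components, proj.coords.shape[1])]

        stage = "select_k"
        sel = clustering.select_k(
            coords, cfg.k_min, cfg.k_max, seed=cfg.seed, restarts=cfg.restarts
        )
        summary["best_k"] = sel.best_k
        summary["silhouette"] = {int(k): float(v) for k, v in sel.silhouette_by_k.items()}
        summary["best_silhouette"] = float(sel.silhouette_by_k[sel.best_k])

        stage = "null_control"
        null_by_k, null_peak = clustering.null_control(
            aln,
            matrix,
            cfg.k_min,
            cfg.k_max,
            seed=cfg.seed,
            n_replicates=cfg.null_replicates,
            mds_components=cfg.mds_components,
            restarts=cfg.restarts,
        )
        summary["null_silhouette"] = {int(k): float(v) for k, v in null_by_k.items()}
        summary["null_peak"] = float(null_peak)
        sil = pd.DataFrame(
            {
                "K": sorted(sel.silhouette_by_k),
                "silhouette": [sel.silhouette_by_k[k] for k in sorted(sel.silhouette_by_k)],
                "null_silhouette": [
                    null_by_k.get(k, float("nan")) for k in sorted(sel.silhouette_by_k)
                ],
            }
        )
        sil.to_csv(emit("silhouette.tsv"), sep="\t", index=False)

        stage = "name_clusters"
        km = clustering.kmeans(coords, sel.best_k, seed=cfg.seed, restarts=cfg.restarts)
        label_map = km.label_map(aln.ids)
        names = clustering.name_clusters(
            label_map, cfg.references, cfg.reference_priority
        )
        assignments = {sid: names[c] for sid, c in label_map.items()}
        with open(emit("assignments.tsv"), "w") as fh:
            fh.write("seq_id\tcluster_index\tcluster_name\n")
            for sid in aln.ids:
                fh.write(f"{sid}\t{label_map[sid]}\t{assignments[sid]}\n")
        summary["cluster_sizes"] = {
            names[c]: int(np.sum(km.labels == c)) for c in sorted(names)
        }

        stage = "contingency_table"
        phylum = _read_map_tsv(cfg.phylum_map) if cfg.phylum_map else {}
        table = contingency_table(assignments, phylum)
        table.to_csv(emit("contingency.tsv"), sep="\t")
        summary["contingency"] = {
            str(p): {str(c): int(v) for c, v in row.items()}
            for p, row in table.iterrows()
        }

        stage = "profile_search"
        if cfg.family_db:
            if not cfg.family_map:
                raise ValueError("family_db given without family_map")
            db_records = read_fasta(cfg.family_db)
            family_of = _read_map_tsv(cfg.family_map)
            db = profile_search.FamilyDatabase(tuple(db_records), family_of)
            background = profile_search.database_background(db.records)
            decoy_len = int(np.median([len(r.residues) for r in db.records]))
            dist_rows: dict[str, dict[str, float]] = {}
            hit_rows = []
            for c in sorted(names):
                members = [sid for sid in aln.ids if label_map[sid] == c]
                cluster_aln = aln.subset(members)
                profile = profile_search.build_profile(cluster_aln, background=background)
                profile = profile_search.calibrate(
                    profile, length=decoy_len, seed=cfg.seed + c
                )
                profile_search.write_profile_tsv(
                    profile, emit(f"profile_{names[c]}.tsv")
                )
                hits = profile_search.search(profile, db, e_threshold=cfg.e_threshold)
                dist_rows[names[c]] = hits.distribution
                for sid, fam, score, ev in hits.hits:
                    hit_rows.append((names[c], sid, fam, score, ev))
            pd.DataFrame(
                hit_rows, columns=["cluster", "seq_id", "family", "score", "evalue"]
            ).to_csv(emit("hits.tsv"), sep="\t", index=False)
            families = sorted({f for d in dist_rows.values() for f in d})
            dist_df = pd.DataFrame(
                {cl: [d.get(f, 0.0) for f in families] for cl, d in dist_rows.items()},
                index=families,
            )
            dist_df.index.name = "family"
            dist_df.to_csv(emit("hit_distribution.tsv"), sep="\t", float_format="%.2f")
            summary["hit_distribution"] = {
                cl: {f: float(v) for f, v in d.items()} for cl, d in dist_rows.items()
            }

        stage = "extract_blocks"
        blocks = blocks_logos.extract_blocks(aln, cfg.max_gap_frac, cfg.min_block_len)
        with open(emit("blocks.tsv"), "w") as fh:
            fh.write("# 0-based, half-open columns\nstart\tend\n")
            for b in blocks:
                fh.write(f"{b.start}\t{b.end}\n")
        summary["n_blocks"] = len(blocks)
        summary["block_columns"] = int(sum(b.end - b.start for b in blocks))

        stage = "logo_matrices"
        block_cols = [c for b in blocks for c in range(b.start, b.end)]
        uniform = np.full(20, 1 / 20)
        for c in sorted(names):
            members = [sid for sid in aln.ids if label_map[sid] == c]
            logo = blocks_logos.logo_matrix(aln, members, uniform, columns=block_cols)
            blocks_logos.write_logo_tsv(logo, emit(f"logo_{names[c]}.tsv"))

        stage = "discriminating_sites"
        ref_numbering = (
            blocks_logos.map_to_reference(aln, cfg.reference_id, cfg.reference_offset)
            if cfg.reference_id
            else None
        )
        cluster_ids = {
            names[c]: [sid for sid in aln.ids if label_map[sid] == c]
            for c in sorted(names)
        }
        sites = blocks_logos.discriminating_sites(
            cluster_ids,
            aln,
            blocks,
            jsd_threshold=cfg.jsd_threshold,
            ref_numbering=ref_numbering,
        )
        with open(emit("sites.tsv"), "w") as fh:
            cl_names = sorted(cluster_ids)
            fh.write("column\tref_number\tdivergence\t" + "\t".join(cl_names) + "\tannotation\n")
            for s in sites:
                consensus = "\t".join(
                    "/".join(s.per_cluster_consensus.get(cl, ())) or "-" for cl in cl_names
                )
                ref = "" if s.ref_number is None else str(s.ref_number)
                fh.write(f"{s.column}\t{ref}\t{s.divergence:.4f}\t{consensus}\t{s.annotation}\n")
        summary["n_discriminating_sites"] = len(sites)

        stage = "summary"
        with open(emit("summary.yaml"), "w") as fh:
            yaml.safe_dump(summary, fh, sort_keys=False)
        return summary
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
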
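"""Readers, writers, configuration, and the end-to-end pipeline runner.

Everything tabular is TSV (tab-separated, UTF-8, '.' decimal).  Sequence
formats go through Biopython; annotation uses the GMT dialect
(term, description, then tab-separated members).  Enrichment tables
print the fold-enrichment score at 4 decimals alongside a full-precision
machine-readable column.  Every pipeline run writes a manifest recording
inputs, parameters, seed, and package version, so reruns with the same
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .design import StudyDesign
from .enrichment import build_design, hypergeom_ora, shared_unique
from .mocklib import (
    combine_offtargets,
    enumerate_kmers,
    hamming_search,
    normalize_sequence,
)
from .multivariate import hcluster, oplsda_vip, pareto_scale, pca
from .sirna import collapse_reads, filter_by_length, map_exact_to_dsrna, profile_reads
from .stats import OmicsMatrix, call_dams, call_degs, missing_value_filter
from . import synthetic

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


# ---------------------------------------------------------------------------
# sequence formats


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, sequence) pairs.

    Identifiers are truncated at the first whitespace (Biopython's
    convention); U is normalized to T with a log notice.  Empty files and
    records without sequence raise :class:`FormatError`.
    """
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} (#{i + 1}) has no sequence")
        norm = normalize_sequence(seq)
        if norm != seq.upper():
            log.info("%s: record %s normalized U->T", path, rec.id)
        records.append((rec.id, norm))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq(path) -> list[tuple[str, str]]:
    records = [
        (rec.id, normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTQ records found")
    return records


def write_fastq(path, records: Iterable[tuple[str, str]]) -> None:
    """Write reads with a constant placeholder quality of 'I' (Q40)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# matrices and annotation


def read_matrix(path, design: StudyDesign) -> OmicsMatrix:
    """Read a feature x sample TSV; empty cells become missing, not zero."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated feature ids {dups[:5]}")
    for col in df.columns:
        try:
            design.line_of(col)
        except ValueError as exc:
            raise ConfigError(f"{path}: column {col!r} does not match the design") from exc
    return OmicsMatrix(df, design)


def write_matrix(path, matrix: OmicsMatrix | pd.DataFrame, index_label: str = "feature") -> None:
    df = matrix.data if isinstance(matrix, OmicsMatrix) else matrix
    df.to_csv(path, sep="\t", index_label=index_label)


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT-like annotation: term, description, members (tab-separated)."""
    annotation: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected term, description, members")
            term, desc, *members = parts
            if term in annotation:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            annotation[term] = set(members)
            names[term] = desc
    if not annotation:
        raise FormatError(f"{path}: no annotation terms found")
    return annotation, names


def write_gmt(path, annotation: Mapping[str, Iterable[str]],
              names: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            desc = (names or {}).get(term, term)
            members = "\t".join(sorted(annotation[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")


def write_feature_list(path, features: Iterable[str]) -> None:
    Path(path).write_text("".join(f"{f}\n" for f in sorted(features)))


def read_feature_list(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def differential_table(records) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows)


def enrichment_table(rows) -> pd.DataFrame:
    """Enrichment rows in the canonical column order, score at 4 decimals
    plus a full-precision column."""
    df = pd.DataFrame(
        {
            "id": [r.term_id for r in rows],
            "term": [r.term_name for r in rows],
            "ListHits": [r.list_hits for r in rows],
            "ListTotal": [r.list_total for r in rows],
            "PopHits": [r.pop_hits for r in rows],
            "PopTotal": [r.pop_total for r in rows],
            "pval": [r.pval for r in rows],
            "padj": [r.padj for r in rows],
            "Enrichment_score": [f"{r.enrichment_score:.4f}" for r in rows],
            "enrichment_score_full": [r.enrichment_score for r in rows],
        }
    )
    return df


# ---------------------------------------------------------------------------
# configuration


_DEFAULT_CONFIG: dict = {
    "seed": 0,
    "design": {
        "lines": list(StudyDesign().lines),
        "roles": dict(StudyDesign().roles),
        "replicates_per_line": 3,
    },
    "simulate": {
        "dsrna_length": 876,
        "gc_fraction": 0.5,
        "n_transcripts": 40,
        "transcript_length_range": [300, 600],
        "planted_sites": [[21, 0], [21, 1], [21, 2], [22, 2], [21, 3]],
        "n_reads": 4000,
        "background_fraction": 0.1,
        "n_genes": 600,
        "n_metabolites": 300,
        "planted_degs": {"DTS_108/TJ806": [20, 3.0]},
        "planted_dams": {"DTS_108/TJ806": [10, 2.0]},
        "missing_rate": 0.1,
        "sigma_log2": 0.25,
        "n_terms": 15,
        "planted_term": ["term_planted", 5.0],
    },
    "scan": {"max_mm": 2, "mode": "all_mock", "k_min": 21, "k_max": 24},
    "profile": {"k": 21, "min_count": 1},
    "deg": {"padj_threshold": 0.05, "fc_up": 2.0, "fc_down": 0.5},
    "dam": {"fc_threshold": 2.0, "p_threshold": 0.05, "two_sided": True},
    "mva": {"n_components": 2, "n_orthogonal": 1},
}


def default_config() -> dict:
    return json.loads(json.dumps(_DEFAULT_CONFIG))  # deep copy


def load_config(path) -> dict:
    """YAML config merged over defaults; unknown keys are rejected."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return merge_config(user)


def merge_config(user: Mapping) -> dict:
    cfg = default_config()
    if "design" not in user and "design" not in cfg:
        raise ConfigError("config missing 'design' block")
    for key, value in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key: {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"config block {key!r} must be a mapping")
            for sub, subval in value.items():
                if sub not in cfg[key]:
                    raise ConfigError(f"unknown config key: {key}.{sub}")
                cfg[key][sub] = subval
        else:
            cfg[key] = value
    if cfg.get("design") is None or not cfg["design"].get("lines"):
        raise ConfigError("config missing 'design' block")
    return cfg


def design_from_config(cfg: Mapping) -> StudyDesign:
    d = cfg["design"]
    return StudyDesign(
        lines=tuple(d["lines"]),
        roles=dict(d["roles"]),
        replicates_per_line=int(d.get("replicates_per_line", 3)),
        seed=int(cfg.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: Mapping | None = None, outdir="pipeline_out") -> dict:
    """Execute the full synthetic-study pipeline and write all artifacts.

    Stages: simulate -> mock library -> off-target scan -> siRNA profile
    -> DEG calling over all pairwise comparisons -> DAM calling -> PCA /
    clustering / OPLS-DA -> Venn set logic -> pathway enrichment.
    Returns a summary dict (also serialized as the manifest) so callers
    can inspect headline numbers without re-reading the TSVs.
    """
    cfg = merge_config(config or {})
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    design = design_from_config(cfg)
    seed = int(cfg["seed"])
    sim = cfg["simulate"]

    # --- simulate -----------------------------------------------------
    dsrna = synthetic.gen_dsrna(sim["dsrna_length"], sim["gc_fraction"], seed)
    transcripts, site_truth = synthetic.gen_transcriptome(
        sim["n_transcripts"],
        tuple(sim["transcript_length_range"]),
        dsrna,
        planted=[tuple(p) for p in sim["planted_sites"]],
        seed=seed + 1,
    )
    reads_raw = synthetic.gen_srna_reads(
        dsrna,
        sim["n_reads"],
        background_fraction=sim["background_fraction"],
        seed=seed + 2,
    )
    planted_degs = {k: tuple(v) for k, v in sim["planted_degs"].items()}
    planted_dams = {k: tuple(v) for k, v in sim["planted_dams"].items()}
    expr, expr_truth = synthetic.gen_expression_study(
        design, sim["n_genes"], planted=planted_degs,
        sigma_log2=sim["sigma_log2"], seed=seed + 3,
    )
    metab, metab_truth = synthetic.gen_metabolome_study(
        design, sim["n_metabolites"], planted=planted_dams,
        missing_rate=sim["missing_rate"], sigma_log2=sim["sigma_log2"],
        seed=seed + 4,
    )
    write_fasta(out / "dsrna.fasta", [(dsrna.id, dsrna.sequence)])
    write_fasta(out / "transcripts.fasta", transcripts)
    write_fastq(out / "reads.fastq", reads_raw)
    write_matrix(out / "expression.tsv", expr, index_label="gene")
    write_matrix(out / "metabolites.tsv", metab, index_label="metabolite")

    # --- mock library + scan ------------------------------------------
    scan_cfg = cfg["scan"]
    kmers = enumerate_kmers(dsrna, scan_cfg["k_min"], scan_cfg["k_max"])
    hits = hamming_search(kmers, transcripts, max_mm=scan_cfg["max_mm"])
    hits_df = pd.DataFrame(
        {
            "kmer": [h.kmer.sequence for h in hits],
            "k": [h.kmer.k for h in hits],
            "strand": [h.kmer.strand for h in hits],
            "kmer_start": [h.kmer.start for h in hits],
            "transcript": [h.transcript_id for h in hits],
            "t_start_1based": [h.start_1based for h in hits],
            "t_end_1based": [h.end_1based for h in hits],
            "mismatches": [h.mismatches for h in hits],
        }
    )
    hits_df.to_csv(out / "offtarget_hits.tsv", sep="\t", index=False)

    # expressed-siRNA evidence: mapped read sequences
    reads = filter_by_length(collapse_reads(reads_raw))
    mapped = map_exact_to_dsrna(reads, dsrna)
    expressed = {a.read.sequence for a in mapped}
    report = combine_offtargets(hits, expressed, mode=scan_cfg["mode"])
    rep_df = pd.DataFrame(
        sorted(report.min_mismatches.items()), columns=["transcript", "min_mismatches"]
    )
    rep_df.to_csv(out / "offtarget_report.tsv", sep="\t", index=False)

    # --- profile -------------------------------------------------------
    prof = profile_reads(reads, dsrna, k=cfg["profile"]["k"],
                         min_count=cfg["profile"]["min_count"])
    pd.DataFrame(
        sorted(prof.size_distribution.items()), columns=["length", "count"]
    ).to_csv(out / "profile_sizes.tsv", sep="\t", index=False)
    cov = pd.DataFrame(prof.first_base_coverage)
    cov.index.name = "position"
    cov.to_csv(out / "profile_coverage.tsv", sep="\t")
    if not prof.base_preference.is_empty:
        pfm_long = prof.base_preference.pfm.reset_index().melt(
            id_vars="position", var_name="base", value_name="frequency"
        )
        pfm_long.to_csv(out / "profile_pfm.tsv", sep="\t", index=False)

    # --- differential calling -----------------------------------------
    comp_design = build_design(design)
    deg_cfg = cfg["deg"]
    deg_records = []
    deg_sets: dict[str, set[str]] = {}
    for comp in comp_design.comparisons:
        recs = call_degs(
            expr, comp.label,
            padj_threshold=deg_cfg["padj_threshold"],
            fc_up=deg_cfg["fc_up"], fc_down=deg_cfg["fc_down"],
        )
        deg_records.extend(recs)
        deg_sets[comp.label] = {r.feature for r in recs if r.call}
    differential_table(deg_records).to_csv(out / "deg.tsv", sep="\t", index=False)

    dam_cfg = cfg["dam"]
    metab_f = missing_value_filter(metab)
    dam_records = []
    dam_sets: dict[str, set[str]] = {}
    for comp in comp_design.comparisons:
        recs = call_dams(
            metab_f, comp.label,
            fc_threshold=dam_cfg["fc_threshold"],
            p_threshold=dam_cfg["p_threshold"],
            two_sided=dam_cfg["two_sided"],
        )
        dam_records.extend(recs)
        dam_sets[comp.label] = {r.feature for r in recs if r.call}
    differential_table(dam_records).to_csv(out / "dam.tsv", sep="\t", index=False)

    # --- multivariate --------------------------------------------------
    mva_cfg = cfg["mva"]
    expr_log = np.log2(expr.data + 1.0)
    expr_pca = pca(expr_log, n_components=mva_cfg["n_components"])
    expr_pca.scores.to_csv(out / "pca_expression_scores.tsv", sep="\t",
                           index_label="sample")
    metab_scaled = pareto_scale(metab_f.data, missing="halfmin")
    metab_pca = pca(metab_scaled.values, n_components=mva_cfg["n_components"])
    metab_pca.scores.to_csv(out / "pca_metabolites_scores.tsv", sep="\t",
                            index_label="sample")
    dendro = hcluster(expr_log, distance="correlation")
    (out / "hclust_expression.nwk").write_text(dendro.to_newick() + "\n")
    classes = {
        s: ("conventional" if design.role(design.line_of(s)) == "conventional"
            else "ge_or_parent")
        for s in metab_f.data.columns
    }
    opls = oplsda_vip(metab_scaled.values, classes,
                      n_orthogonal=mva_cfg["n_orthogonal"])
    opls.vip.to_frame().to_csv(out / "vip.tsv", sep="\t", index_label="metabolite")

    # --- venn ----------------------------------------------------------
    group1 = [c.label for c in comp_design.by_group(1)]
    venn_rows = []
    if len(group1) >= 2:
        summary = shared_unique({c: deg_sets[c] for c in group1[:4]})
        for members, elems in sorted(summary.regions.items(), key=lambda kv: sorted(kv[0])):
            venn_rows.append({
                "region": "&".join(sorted(members)),
                "n": len(elems),
                "features": ",".join(sorted(elems)),
            })
    pd.DataFrame(venn_rows).to_csv(out / "venn_group1_degs.tsv", sep="\t", index=False)

    # --- enrichment -----------------------------------------------------
    annotation, term_truth = synthetic.gen_annotation(
        expr.features,
        n_terms=sim["n_terms"],
        planted_term=tuple(sim["planted_term"]),
        target_list=sorted(deg_sets.get(next(iter(planted_degs), ""), set()))
        or expr.features[:20],
        seed=seed + 5,
    )
    write_gmt(out / "annotation.gmt", annotation)
    universe = set(expr.features) & set().union(*annotation.values())
    enr_frames = []
    for comp_label, features in deg_sets.items():
        if not features:
            continue
        rows = hypergeom_ora(features, annotation, universe)
        df = enrichment_table(rows)
        df.insert(0, "comparison", comp_label)
        enr_frames.append(df)
    enr = pd.concat(enr_frames, ignore_index=True) if enr_frames else pd.DataFrame()
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    # --- manifest -------------------------------------------------------
    summary = {
        "version": __version__,
        "seed": seed,
        "parameters": cfg,
        "design": {"lines": list(design.lines), "replicates": design.replicates_per_line},
        "n_mock_kmers": len(kmers),
        "n_offtarget_transcripts": report.n_transcripts,
        "offtarget_tiers": {str(k): v for k, v in report.tier_counts.items()},
        "planted_sites": [dataclasses.asdict(s) for s in site_truth.offtarget_sites],
        "total_mapped_reads": prof.total_mapped,
        "n_comparisons": len(comp_design.comparisons),
        "deg_counts": {c: len(s) for c, s in deg_sets.items()},
        "dam_counts": {c: len(s) for c, s in dam_sets.items()},
        "pca_expression_evr": [float(x) for x in expr_pca.explained_variance],
        "pca_metabolites_evr": [float(x) for x in metab_pca.explained_variance],
        "vip_mean_square": float((opls.vip**2).mean()),
        "planted_enriched_term": sorted(term_truth.enriched_terms),
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    manifest = json.dumps(summary, indent=2, sort_keys=True)
    (out / "manifest.json").write_text(manifest + "\n")
    return summary
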
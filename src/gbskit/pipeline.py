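"""End-to-end orchestration of the GBS analysis stages.

The pipeline binds the stages digest -> ontarget -> filter -> diversity ->
ancestry through a single declarative :class:`PipelineConfig`.  Every
threshold defaults to the study's value (size window 200–700 bp, QD > 2,
FS < 60, MQ >= 40, MAF > 0.05, missingness <= 20%, rare threshold 3,
B = 2000 bootstrap pseudo-replicates).  Outputs are plain TSV tables with
commented headers so each figure-equivalent table is diffable.

``run_demo`` generates a complete synthetic input bundle with
:mod:`gbskit.synthetic` and runs every stage on it — a self-contained
smoke test of the whole pipeline.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from gbskit import ancestry as anc
from gbskit import diversity as div
from gbskit import io as gio
from gbskit import synthetic as syn
from gbskit.digest import (
    BSAXI,
    EnzymeSpec,
    Fragment,
    SizeWindow,
    digest_genome,
    fragment_histogram,
    size_select,
)
from gbskit.ontarget import IntervalSet, intersect
from gbskit.variant_filter import (
    GenotypeMatrix,
    apply_hard_filters,
    classify_substitutions,
    filter_population,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("digest", "ontarget", "filter", "diversity", "ancestry")


@dataclass
class PipelineConfig:
    """Paths and thresholds binding the pipeline stages together."""

    # inputs
    fasta: str | None = None
    observed_bed: str | None = None
    vcf: str | None = None
    reference_vcf: str | None = None
    labels: str | None = None
    # enzyme
    enzyme_name: str = BSAXI.name
    enzyme_recognition: str = BSAXI.recognition
    cut_upstream: int = BSAXI.cut_upstream
    cut_downstream: int = BSAXI.cut_downstream
    both_strands: bool = True
    # digest / ontarget
    size_min: int = 200
    size_max: int = 700
    bin_width: int = 50
    include_terminal: bool = False
    min_overlap: int = 1
    # filters
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    maf_min: float = 0.05
    max_missing: float = 0.20
    # diversity
    rare_threshold: int = 3
    # ancestry
    bootstrap_B: int = 2000
    tol: float = 1e-7
    max_iter: int = 2000
    # run control
    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    def enzyme(self) -> EnzymeSpec:
        return EnzymeSpec(
            self.enzyme_name,
            self.enzyme_recognition,
            self.cut_upstream,
            self.cut_downstream,
            self.both_strands,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _write_tsv(path: Path, frame: pd.DataFrame, params: dict[str, Any]) -> None:
    header = "".join(f"# {k} = {v}\n" for k, v in params.items())
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def _required(config: PipelineConfig) -> list[str]:
    need = []
    if "digest" in config.stages:
        need.append("fasta")
    if "ontarget" in config.stages:
        need.append("observed_bed")
        if "digest" not in config.stages:
            need.append("predicted digest (enable the digest stage)")
    if {"filter", "diversity"} & set(config.stages):
        need.append("vcf")
    if "ancestry" in config.stages:
        need += ["vcf", "reference_vcf", "labels"]
    return need


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the configured stages in order; returns the output file map.

    Raises before any stage runs if a referenced input file is missing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gbskit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        for attr in ("fasta", "observed_bed", "vcf", "reference_vcf", "labels"):
            path = getattr(config, attr)
            needed = any(attr in r for r in _required(config))
            if needed and (path is None or not Path(path).exists()):
                raise FileNotFoundError(
                    f"pipeline input '{attr}' missing or not found: {path}"
                )
        outputs: dict[str, Path] = {"log": log_path}
        params = dataclasses.asdict(config)
        window = SizeWindow(config.size_min, config.size_max)
        selected_fragments: list[Fragment] | None = None
        matrix: GenotypeMatrix | None = None

        if "digest" in config.stages:
            sequences = gio.read_fasta(config.fasta)
            fragments, _cuts = digest_genome(sequences, config.enzyme())
            total_bp = sum(len(s) for s in sequences.values())
            sel = size_select(fragments, window, total_bp, config.include_terminal)
            selected_fragments = sel.selected
            logger.info(
                "digest: %d fragments, %d selected (%d bp, %.4f of genome)",
                len(fragments), sel.count, sel.total_bp, sel.genome_fraction or 0.0,
            )
            bed = outdir / "digest_selected.bed"
            gio.write_bed(bed, sel.selected)
            outputs["digest_bed"] = bed
            rows = []
            for chrom in sequences:
                cf = [f for f in sel.selected if f.chromosome == chrom]
                bp = sum(f.length for f in cf)
                rows.append((chrom, len(cf), bp, bp / len(sequences[chrom])))
            summary = pd.DataFrame(rows, columns=["chromosome", "n_fragments", "total_bp", "fraction"])
            out = outdir / "digest_summary.tsv"
            _write_tsv(out, summary, params)
            outputs["digest_summary"] = out
            edges, counts = fragment_histogram(sel.selected, config.bin_width, window)
            hist = pd.DataFrame(
                {"bin_start": edges[:-1], "bin_end": edges[1:], "n_fragments": counts}
            )
            out = outdir / "digest_histogram.tsv"
            _write_tsv(out, hist, params)
            outputs["digest_histogram"] = out

        if "ontarget" in config.stages:
            if selected_fragments is None:
                raise RuntimeError("ontarget stage needs the digest stage's output")
            observed = IntervalSet(gio.read_bed(config.observed_bed), name="observed")
            predicted = IntervalSet(list(selected_fragments), name="predicted")
            res = intersect(observed, predicted, config.min_overlap)
            n_hits = int(res["hit"].sum())
            table = pd.DataFrame(
                [("observed", len(observed), n_hits, 100.0 * n_hits / len(observed))],
                columns=["sample", "n_observed", "n_hits", "percent"],
            )
            logger.info("ontarget: %d/%d observed fragments on target", n_hits, len(observed))
            out = outdir / "ontarget.tsv"
            _write_tsv(out, table, params)
            outputs["ontarget"] = out

        if {"filter", "diversity", "ancestry"} & set(config.stages):
            records, samples = gio.read_vcf(config.vcf)
            passing, removed = apply_hard_filters(
                records, config.qd_min, config.fs_max, config.mq_min
            )
            matrix, counts = filter_population(
                passing, samples, config.maf_min, config.max_missing
            )
            logger.info(
                "filter: %d input sites, hard-filter removals %s, survivors %s",
                len(records), removed, counts,
            )

        if "filter" in config.stages:
            assert matrix is not None
            out = outdir / "filtered.vcf"
            kept = {
                (c, p) for c, p in zip(matrix.loci["chromosome"], matrix.loci["pos"])
            }
            retained = [r for r in passing if (r.chromosome, r.pos) in kept]
            gio.write_vcf(out, retained, samples)
            outputs["filtered_vcf"] = out
            report = pd.DataFrame(
                [("hard_" + k, v) for k, v in removed.items()]
                + [(k, v) for k, v in counts.items()],
                columns=["step", "count"],
            )
            rep = outdir / "filter_report.tsv"
            _write_tsv(rep, report, params)
            outputs["filter_report"] = rep
            subs = classify_substitutions(matrix)
            out = outdir / "substitutions.tsv"
            _write_tsv(out, subs.to_frame(), params)
            outputs["substitutions"] = out

        if "diversity" in config.stages:
            assert matrix is not None
            per_site, means = div.site_stats(matrix)
            out = outdir / "diversity_sites.tsv"
            _write_tsv(out, per_site, params)
            outputs["diversity_sites"] = out
            taj = div.tajimas_d(matrix)
            sfs = div.folded_sfs(matrix, config.rare_threshold)
            summary = pd.DataFrame(
                [
                    ("mean_He", means["He"]),
                    ("mean_Ho", means["Ho"]),
                    ("mean_PIC", means["PIC"]),
                    ("tajimas_D", taj.D if taj.D is not None else float("nan")),
                    ("segregating_sites", taj.S),
                    ("proportion_rare", sfs.proportion_rare),
                ],
                columns=["statistic", "value"],
            )
            out = outdir / "diversity_summary.tsv"
            _write_tsv(out, summary, params)
            outputs["diversity_summary"] = out
            out = outdir / "sfs.tsv"
            _write_tsv(out, sfs.to_frame(), params)
            outputs["sfs"] = out

        if "ancestry" in config.stages:
            assert matrix is not None
            ref_records, ref_samples = gio.read_vcf(config.reference_vcf)
            ref_matrix, _ = filter_population(ref_records, ref_samples, 0.0, 1.0)
            labels = gio.read_labels(config.labels)
            test_h, panel = anc.intersect_panels(matrix, ref_matrix, labels)
            logger.info(
                "ancestry: %d shared loci, K=%d populations", panel.n_loci, panel.K
            )
            q = anc.estimate_q_matrix(test_h, panel, config.tol, config.max_iter)
            out = outdir / "q_matrix.tsv"
            gio.write_q_matrix(out, q)
            outputs["q_matrix"] = out
            rows = []
            for i, sample in enumerate(test_h.samples):
                boot = anc.bootstrap_q(
                    test_h.doses[i], panel, B=config.bootstrap_B,
                    seed=config.seed + i, tol=config.tol, max_iter=config.max_iter,
                )
                for k, pop in enumerate(panel.populations):
                    rows.append((sample, pop, boot.bias[k], boot.se[k]))
            boot_table = pd.DataFrame(rows, columns=["sample", "population", "bias", "se"])
            out = outdir / "bootstrap.tsv"
            _write_tsv(out, boot_table, params)
            outputs["bootstrap"] = out
            joint = GenotypeMatrix(
                samples=ref_matrix.samples + test_h.samples,
                loci=panel.loci.copy(),
                doses=np.vstack(
                    [
                        _align_doses(ref_matrix, panel),
                        test_h.doses,
                    ]
                ),
            )
            res = anc.pca(joint, n_components=min(10, joint.n_samples))
            pcs = pd.DataFrame(
                res.coordinates,
                columns=[f"PC{i + 1}" for i in range(res.coordinates.shape[1])],
            )
            pcs.insert(0, "sample", res.samples)
            out = outdir / "pca.tsv"
            _write_tsv(
                out,
                pcs,
                {**params, "variance_fractions": ",".join(
                    f"{v:.4f}" for v in res.variance_fractions)},
            )
            outputs["pca"] = out

        logger.info("pipeline complete: %d outputs in %s", len(outputs), outdir)
        return outputs
    finally:
        root.removeHandler(handler)
        handler.close()


def _align_doses(reference: GenotypeMatrix, panel: anc.ReferencePanel) -> np.ndarray:
    """Reference doses restricted to the panel's loci, in panel order."""
    pos_of = {
        (c, p): i
        for i, (c, p) in enumerate(
            zip(reference.loci["chromosome"], reference.loci["pos"])
        )
    }
    idx = [pos_of[(c, p)] for c, p in zip(panel.loci["chromosome"], panel.loci["pos"])]
    return reference.doses[:, idx]


def run_demo(outdir: str | Path, seed: int = 1, bootstrap_B: int = 25) -> dict[str, Path]:
    """Generate a synthetic input bundle and run every pipeline stage on it.

    The demo plants recognition sites in a toy genome, simulates observed
    fragment spans at 75% on-target, a filter-exercising VCF, and a K=3
    Balding–Nichols panel with admixed test samples.  All randomness
    derives from ``seed``; rerunning with the same seed reproduces every
    output byte for byte.
    """
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # genome with planted sites spaced so internal fragments fall in-window
    positions = list(range(500, 19_000, 600))
    genome_cfg = syn.SimGenomeConfig(
        length=20_000,
        n_chromosomes=1,
        gc_content=0.4,
        planted_sites=[(0, p, "+") for p in positions],
        seed=int(rng.integers(2**31)),
    )
    sequences, _truth = syn.simulate_genome(genome_cfg, BSAXI)
    fasta = inputs / "genome.fa"
    gio.write_fasta(fasta, sequences)

    fragments, _ = digest_genome(sequences, BSAXI)
    window = SizeWindow(200, 700)
    sel = size_select(fragments, window, sum(map(len, sequences.values())))
    observed = []
    for f in sel.selected:
        if rng.random() < 0.75:
            observed.append((f.chromosome, f.start, f.end))
        else:
            shift = int(rng.integers(2_000, 5_000))
            start = (f.start + shift) % (20_000 - f.length)
            observed.append((f.chromosome, start, start + f.length))
    observed_bed = inputs / "observed.bed"
    with open(observed_bed, "w") as fh:
        for chrom, s, e in observed:
            fh.write(f"{chrom}\t{s}\t{e}\n")

    # structured panel + admixed individuals; shared loci become the test VCF
    panel_cfg = syn.SimPanelConfig(
        K=3, n_loci=400, n_per_pop=10, fst=0.15, seed=int(rng.integers(2**31))
    )
    sim_panel = syn.simulate_reference_panel(panel_cfg)
    true_q = np.array(
        [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [0.7, 0.3, 0.0],
         [0.5, 0.5, 0.0], [0.2, 0.3, 0.5], [0.6, 0.2, 0.2], [0.3, 0.3, 0.4],
         [0.9, 0.1, 0.0], [0.1, 0.8, 0.1], [0.4, 0.6, 0.0], [0.25, 0.25, 0.5]]
    )
    adm_cfg = syn.SimAdmixedConfig(
        true_Q=true_q, missing_rate=0.02, seed=int(rng.integers(2**31))
    )
    admixed = syn.simulate_admixed(sim_panel.panel, adm_cfg)

    test_records = records_from_matrix(admixed.genotypes)
    defect_records, _labels, _defect_samples = syn.simulate_variant_file(
        60,
        n_samples=len(admixed.genotypes.samples),
        frac_indel=0.1,
        frac_multiallelic=0.1,
        frac_low_maf=0.15,
        frac_high_missing=0.1,
        frac_hard_fail=0.15,
        seed=int(rng.integers(2**31)),
    )
    for r in defect_records:  # place after the panel loci on another chromosome
        r.chromosome = "2"
    test_vcf = inputs / "test.vcf"
    gio.write_vcf(test_vcf, test_records + defect_records, admixed.genotypes.samples)

    ref_vcf = inputs / "reference.vcf"
    gio.write_vcf(
        ref_vcf, records_from_matrix(sim_panel.genotypes), sim_panel.genotypes.samples
    )
    labels_tsv = inputs / "labels.tsv"
    gio.write_labels(labels_tsv, sim_panel.labels)
    gio.write_q_matrix(inputs / "true_q.tsv", admixed.true_Q)

    config = PipelineConfig(
        fasta=str(fasta),
        observed_bed=str(observed_bed),
        vcf=str(test_vcf),
        reference_vcf=str(ref_vcf),
        labels=str(labels_tsv),
        bootstrap_B=bootstrap_B,
        seed=seed,
    )
    config.to_yaml(outdir / "config.yaml")
    return run_pipeline(config, outdir)


def records_from_matrix(matrix: GenotypeMatrix, qd: float = 25.0, fs: float = 1.0,
                        mq: float = 55.0):
    """Turn a genotype matrix back into VCF-writable records (passing annotations)."""
    from gbskit.variant_filter import VariantRecord

    records = []
    for j in range(matrix.n_loci):
        records.append(
            VariantRecord(
                chromosome=str(matrix.loci["chromosome"].iat[j]),
                pos=int(matrix.loci["pos"].iat[j]),
                ref=str(matrix.loci["ref"].iat[j]),
                alt=(str(matrix.loci["alt"].iat[j]),),
                qd=qd,
                fs=fs,
                mq=mq,
                genotypes=matrix.doses[:, j],
            )
        )
    return records
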
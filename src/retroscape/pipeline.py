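"""End-to-end demo pipeline: simulate → detect → annotate → date →
abundance → IRAP → proximity, with a manifest for reproducibility.

All stage randomness derives from the single run seed via spawned seed
sequences, so a re-run with the same configuration reproduces every output.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, abundance, annotate, dating, detect, irap, proximity
from .io import write_bed, write_fasta, write_fastq, write_gff3
from .simulate import (DEFAULT_RATE, build_genome, default_templates,
                       generate_differentiated_truth, plant_primer_sites,
                       simulate_marker_population, simulate_reads)
from .structure import DominantAdmixture


@dataclass
class RunConfig:
    """Pipeline thresholds and study parameters (defaults are desk-scale)."""

    seed: int = 0
    rate: float = DEFAULT_RATE
    # simulate
    background_length: int = 400_000
    n_lineages: int = 4
    elements_per_lineage_age: int = 3
    element_ages_mya: tuple[float, ...] = (1.0, 2.0)
    nesting_fraction: float = 0.0
    n_solo_ltr: int = 4
    n_fragments: int = 4
    gene_count: int = 40
    coverage: float = 5.0
    read_length: int = 85
    read_error_rate: float = 0.002
    # detect
    min_ltr: int = 100
    max_ltr: int = 3000
    min_elem: int = 1000
    max_elem: int = 16000
    min_ltr_identity: float = 85.0
    # annotate
    min_domain_score: float = 250.0
    # dating
    age_bin_width_mya: float = 0.25
    # irap / structure
    primer: str = "TTCAAGAATCACACCCTCTA"
    n_accessions: int = 12
    n_marker_loci: int = 40
    k_true: int = 2
    k_range: tuple[int, ...] = (1, 2, 3, 4)
    n_replicates: int = 7
    band_size_tolerance: float = 0.02
    # proximity (flank scaled to the demo genome; the field-standard window
    # is 100 kb around each gene)
    flank_bp: int = 5_000
    n_focal_genes: int = 12
    n_planted_sites: int = 12

    def validate(self) -> None:
        if not (self.min_ltr <= self.max_ltr and self.min_elem <= self.max_elem):
            raise ValueError("inconsistent length bounds")
        if not 0 <= self.min_ltr_identity <= 100:
            raise ValueError("min_ltr_identity must be a percentage")
        if self.rate <= 0 or self.coverage <= 0:
            raise ValueError("rate and coverage must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(path.read_text()) or {}
        elif path.suffix == ".toml":
            import tomllib
            data = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"unsupported config format {path.suffix!r}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("element_ages_mya", "k_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to
    ``manifest.json``)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stage_seeds": seeds, "config": asdict(config),
                      "stages": {}, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    stage = "simulate"
    try:
        templates = default_templates(config.n_lineages)
        specs = [(t.lineage_name, age, config.elements_per_lineage_age)
                 for t in templates for age in config.element_ages_mya]
        sg = build_genome(templates, specs,
                          background_length=config.background_length,
                          gene_count=config.gene_count,
                          nesting_fraction=config.nesting_fraction,
                          seed=seeds[0], rate=config.rate,
                          n_solo_ltr=config.n_solo_ltr,
                          n_fragments=config.n_fragments,
                          primer_sites_spec=[(config.primer,
                                              config.n_planted_sites)])
        # enrich: one extra site in the flank of every other focal gene
        focal_genes = sg.genes[:config.n_focal_genes]
        rng_plant = np.random.default_rng(seeds[2])
        chrom = next(iter(sg.genome))
        seq_list = list(sg.genome.sequences[chrom])
        for g in focal_genes[::2]:
            seg = next((s for s in sg.background_segments
                        if s[0] == g.chrom and s[1] <= g.start <= s[2]), None)
            if seg is None:
                continue
            window = [(g.chrom, max(seg[1], g.start - config.flank_bp),
                       min(seg[2], g.end + config.flank_bp))]
            sg.primer_sites += plant_primer_sites(
                seq_list, config.primer, window, 1, rng_plant, chrom)
        sg.genome.sequences[chrom] = "".join(seq_list)
        write_fasta(sg.genome, outdir / "genome.fasta")
        write_gff3(sg.truth_gff(), outdir / "truth.gff3")
        write_bed(sg.genes, outdir / "genes.bed")
        reads = simulate_reads(sg.genome, coverage=config.coverage,
                               read_length=config.read_length,
                               error_rate=config.read_error_rate,
                               seed=seeds[1])
        write_fastq(reads, outdir / "reads.fastq")
        manifest["stages"][stage] = {"elements": len(sg.elements),
                                     "genes": len(sg.genes),
                                     "reads": len(reads)}

        stage = "detect"
        elements = detect.detect_elements(
            sg.genome, k=20, min_ltr=config.min_ltr, max_ltr=config.max_ltr,
            min_elem=config.min_elem, max_elem=config.max_elem,
            min_identity=config.min_ltr_identity)
        write_gff3(detect.elements_to_gff(elements), outdir / "elements.gff3")
        bench = detect.evaluate(elements, sg.elements)
        manifest["stages"][stage] = {"candidates_retained": len(elements),
                                     **{k: round(v, 4) if isinstance(v, float)
                                        else v for k, v in bench.items()}}

        stage = "annotate"
        reference = annotate.reference_from_templates(templates)
        seqs = {el.element_id: sg.genome.fetch(el.chrom, el.start, el.end)
                for el in elements}
        annotations = annotate.annotate_elements(
            seqs, reference, min_score=config.min_domain_score)
        annotate.annotation_table(annotations).to_csv(
            outdir / "annotations.tsv", sep="\t", index=False)
        n_auto = sum(a.autonomous for a in annotations.values())
        manifest["stages"][stage] = {
            "annotated": len(annotations), "autonomous": n_auto,
            "undetermined": sum(a.lineage == "undetermined"
                                for a in annotations.values())}

        stage = "dating"
        lineages = {eid: a.lineage for eid, a in annotations.items()}
        estimates, n_sat = dating.date_elements(elements, sg.genome,
                                                rate=config.rate,
                                                lineages=lineages)
        pd.DataFrame([{"element_id": e.id, "lineage": e.lineage,
                       "K": e.K, "T_mya": e.T} for e in estimates]).to_csv(
            outdir / "ages.tsv", sep="\t", index=False)
        profile = dating.age_profile(estimates,
                                     bin_width_mya=config.age_bin_width_mya)
        manifest["stages"][stage] = {
            "dated": len(estimates), "saturated_excluded": n_sat,
            "mean_age_mya": round(profile.mean_age, 3),
            "peak_ages_mya": [round(p, 2) for p in profile.peak_ages]}

        stage = "abundance"
        assignments = abundance.map_reads(reads, seqs)
        table = abundance.proportions(assignments, annotations)
        table.to_csv(outdir / "abundance.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "mapped_fraction": round(abundance.mapped_fraction(table), 4),
            "truth_element_fraction": round(sg.element_fraction, 4)}

        stage = "irap"
        sites = irap.find_primer_sites(sg.genome, config.primer,
                                       enforce_length=False)
        amplicons = irap.predict_amplicons(sites)
        truth_pop = generate_differentiated_truth(
            config.n_accessions, config.k_true, config.n_marker_loci,
            seed=seeds[4])
        matrix = simulate_marker_population(truth_pop, seed=seeds[5])
        matrix.to_csv(outdir / "irap_matrix.tsv", sep="\t")
        model = DominantAdmixture(matrix)
        fit = model.fit(config.k_true, n_replicates=config.n_replicates,
                        seed=seeds[6])
        fit.q_frame().to_csv(outdir / "q_matrix.tsv", sep="\t")
        ev = model.select_k(config.k_range,
                            n_replicates=config.n_replicates, seed=seeds[6])
        ev.table.to_csv(outdir / "delta_k.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "primer_sites": len(sites), "amplicons": len(amplicons),
            "selected_k": ev.selected_k, "k_true": config.k_true}

        stage = "proximity"
        control_genes = proximity.sample_control_genes(
            sg.genes, focal_genes, n=config.n_focal_genes, seed=seeds[7])
        chrom_lengths = {c: sg.genome.length(c) for c in sg.genome}
        fc = proximity.count_proximal(focal_genes, sites, chrom_lengths,
                                      flank_bp=config.flank_bp,
                                      gene_set="focal")
        cc = proximity.count_proximal(control_genes, sites, chrom_lengths,
                                      flank_bp=config.flank_bp,
                                      gene_set="control")
        test = proximity.enrichment_test(fc, cc)
        manifest["stages"][stage] = {
            "focal_with_hit": fc.n_with_hit, "control_with_hit": cc.n_with_hit,
            "chi2": round(test.statistic, 4), "p_value": round(test.p_value, 6)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
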
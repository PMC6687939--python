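"""Shared IO, configuration and the end-to-end SIP pipeline.

Stages: simulate a community and its density gradients -> qPCR heavy-fraction
selection -> heavy-window count matrices -> negative-binomial enrichment
calling -> ANI-based population delineation of the enriched genomes -> a
machine-readable report, plus a thermodynamic summary of the syntrophic
chain. All randomness flows from the single config seed through named
per-stage substreams, so identical config + seed gives a byte-identical
report.

Formats are plain text: TSV tables, FASTA genomes, Newick dendrograms,
key=value configs, JSON reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import enrichment, fraction_select, genome_compare, sip_synth, thermo
from .enrichment import CountMatrix
from .fraction_select import QPCRProfile

__all__ = [
    "REPORT_SCHEMA_VERSION",
    "PipelineConfig",
    "read_config",
    "run_pipeline",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_fasta",
    "write_fasta",
    "read_qpcr_tsv",
    "write_qpcr_tsv",
    "write_truth_tsv",
]

logger = logging.getLogger("sipsyn")

REPORT_SCHEMA_VERSION = "1.0"

# substream names, in pipeline order; each gets its own derived seed
_STAGES = ("community", "qpcr", "counts", "genomes")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Every tunable of the synthetic end-to-end run, with documented defaults.

    Density-scale note: on the Schildkraut scale used by the simulator,
    fully 13C-labeled DNA of mid-GC organisms bands at ~1.73-1.77 g/mL, so the
    default sequencing window covers that band. ``select_window`` defaults to
    the same window so the qPCR selection stage and the sequenced window agree.
    """

    seed: int = 0
    # community
    n_populations: int = 50
    n_labeled: int = 2
    abundance_distribution: str = "lognormal"
    gc_min: float = 0.35
    gc_max: float = 0.65
    # gradient
    n_fractions: int = 24
    density_min: float = 1.66
    density_max: float = 1.78
    sigma_density: float = 0.003
    carryover: float = 0.01
    # qPCR selection
    qpcr_noise_cv: float = 0.1
    ratio_threshold: float = 2.0
    select_window_lo: float = 1.73
    select_window_hi: float = 1.77
    # sequencing
    replicates: int = 2
    depth: int = 500_000
    dispersion: float = 0.05
    count_mode: str = "nb"
    heavy_window_lo: float = 1.73
    heavy_window_hi: float = 1.77
    # enrichment calling
    alpha: float = 0.05
    use_bh: bool = True
    lfc_min: float = 0.0
    # ANI stage
    run_ani: bool = True
    ani_genome_length: int = 30_000
    population_cut: float = 1.0
    species_cut: float = 5.0
    # thermodynamic summary
    dg0_prime: float = 53.0
    temperature: float = 298.15
    ph: float = 7.0
    butyrate_mM: float = 1.0
    acetate_mM: float = 1.0
    h2_Pa: float = 1.0
    dg_threshold: float = -10.0

    @classmethod
    def from_dict(cls, values: Mapping[str, str]) -> "PipelineConfig":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, raw in values.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            ftype = fields[key].type
            if ftype == "bool":
                kwargs[key] = str(raw).strip().lower() in ("1", "true", "yes", "on")
            elif ftype == "int":
                kwargs[key] = int(raw)
            elif ftype == "float":
                kwargs[key] = float(raw)
            else:
                kwargs[key] = str(raw)
        return cls(**kwargs)


def read_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file (# comments allowed)."""
    values: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, val = stripped.partition("=")
        values[key.strip()] = val.strip()
    return PipelineConfig.from_dict(values)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_counts_tsv(matrix: CountMatrix, path) -> None:
    """Write a feature x sample count TSV with condition/replicate header rows."""
    samples = list(matrix.counts.columns)
    lines = [
        "#condition\t" + "\t".join(matrix.conditions[s] for s in samples),
        "#replicate\t" + "\t".join(matrix.replicates.get(s, "1") for s in samples),
        "feature\t" + "\t".join(samples),
    ]
    for fid, row in matrix.counts.iterrows():
        lines.append(str(fid) + "\t" + "\t".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts_tsv(path) -> CountMatrix:
    """Read a count TSV written by :func:`write_counts_tsv`.

    Raises a parse error naming the offending line/column on malformed or
    negative entries.
    """
    lines = Path(path).read_text().splitlines()
    conditions_row = replicates_row = None
    header = None
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#condition"):
            conditions_row = line.split("\t")[1:]
        elif line.startswith("#replicate"):
            replicates_row = line.split("\t")[1:]
        elif line.startswith("#"):
            continue
        else:
            header = line.split("\t")
            data_start = i + 1
            break
    if header is None or len(header) < 2:
        raise ValueError(f"{path}: no sample header found")
    samples = header[1:]
    if conditions_row is None or len(conditions_row) != len(samples):
        raise ValueError(f"{path}: missing or misaligned #condition row")
    if replicates_row is None:
        replicates_row = ["1"] * len(samples)
    features, rows = [], []
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(samples) + 1:
            raise ValueError(
                f"{path}:{lineno}: expected {len(samples) + 1} columns, got {len(parts)}"
            )
        vals = []
        for col, part in enumerate(parts[1:], start=2):
            try:
                v = int(part)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: column {col}: not an integer: {part!r}"
                ) from None
            if v < 0:
                raise ValueError(f"{path}:{lineno}: column {col}: negative count {v}")
            vals.append(v)
        features.append(parts[0])
        rows.append(vals)
    counts = pd.DataFrame(rows, index=features, columns=samples)
    return CountMatrix(
        counts=counts,
        conditions=dict(zip(samples, conditions_row)),
        replicates=dict(zip(samples, replicates_row)),
    )


def write_fasta(records: Sequence[tuple[str, str]], path, width: int = 60) -> None:
    """Write (id, sequence) records as wrapped FASTA."""
    seqs = [SeqRecord(Seq(seq), id=str(rid), description="") for rid, seq in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqs)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records, tolerating wrapped lines and mixed case.

    Sequences are normalized to upper case.
    """
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_qpcr_tsv(profiles: Sequence[QPCRProfile], path) -> None:
    """Write qPCR profiles as TSV: fraction, density_g_ml, signal, condition, replicate."""
    lines = ["fraction\tdensity_g_ml\tsignal\tcondition\treplicate"]
    for prof in profiles:
        for i, (d, s) in enumerate(zip(prof.densities, prof.signals), start=1):
            lines.append(f"{i}\t{d:.6g}\t{s:.10g}\t{prof.condition}\t{prof.replicate}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_qpcr_tsv(path) -> list[QPCRProfile]:
    """Read qPCR profiles grouped by (condition, replicate)."""
    df = pd.read_csv(path, sep="\t")
    required = {"density_g_ml", "signal", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    profiles = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("density_g_ml")
        profiles.append(
            QPCRProfile(
                densities=tuple(grp["density_g_ml"]),
                signals=tuple(grp["signal"]),
                condition=str(cond),
                replicate=str(rep),
            )
        )
    return profiles


def write_truth_tsv(community: Sequence[sip_synth.GenomePopulation], path) -> None:
    lines = ["id\tis_labeled\tgc\trel_abundance\tatom13c"]
    for pop in community:
        lines.append(
            f"{pop.id}\t{str(pop.is_labeled).lower()}\t{pop.gc:.6f}"
            f"\t{pop.rel_abundance:.8g}\t{pop.atom13c:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage_seeds(seed: int) -> dict[str, int]:
    """Named integer substream seeds derived from the single config seed."""
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 2**31 - 1, size=len(_STAGES))
    return {name: int(s) for name, s in zip(_STAGES, draws)}


def _thermo_summary(config: PipelineConfig) -> dict:
    conditions = thermo.EnvironmentalConditions(
        temperature=config.temperature,
        pH=config.ph,
        activities={
            "butyrate": config.butyrate_mM * 1e-3,
            "acetate": config.acetate_mM * 1e-3,
            "H2": config.h2_Pa * 1e-5,
        },
    )
    rxn = thermo.BUTYRATE_OXIDATION
    dg = thermo.delta_g(rxn, config.dg0_prime, conditions)
    acetate_threshold = thermo.threshold_activity(
        rxn, config.dg0_prime, conditions, "acetate", config.dg_threshold
    )
    butyrate_yields = [
        ("acetogen", -21.1),
        ("hydrogenotrophic_methanogen", -9.4),
        ("acetoclastic_methanogen", -58.9),
    ]
    shares = thermo.partition_energy(butyrate_yields)
    species = thermo.default_species_table()
    bmp = thermo.theoretical_methane_volume(0.040, 0.010, species["butyric_acid"], 308.15)
    return {
        "delta_g_kj_mol": round(dg, 1),
        "acetate_threshold_mM": round(acetate_threshold * 1e3, 1),
        "energy_partition_pct": {g: round(100 * f) for g, f in shares.items()},
        "theoretical_methane_mL": round(bmp, 1),
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run simulate -> select -> count -> enrich -> ANI -> report.

    Returns the report dict; if ``outdir`` is given, also writes all
    intermediate tables (TSV/FASTA/Newick) and ``report.json`` there.
    Identical config and seed give a byte-identical report.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
    }

    stage = "community"
    try:
        logger.info("stage %s: %d populations, %d labeled, seed %d",
                    stage, config.n_populations, config.n_labeled, seeds[stage])
        community = sip_synth.simulate_community(
            config.n_populations,
            config.n_labeled,
            abundance_distribution=config.abundance_distribution,
            seed=seeds["community"],
            gc_range=(config.gc_min, config.gc_max),
        )
        labeled_ids = [p.id for p in community if p.is_labeled]
        report["community"] = {
            "n_populations": config.n_populations,
            "labeled_ids": labeled_ids,
        }

        stage = "gradient"
        edges = np.linspace(config.density_min, config.density_max, config.n_fractions + 1)
        profiles = {
            cond: sip_synth.simulate_gradient(
                community,
                edges,
                sigma_density=config.sigma_density,
                condition=cond,
                carryover=config.carryover,
            )
            for cond in ("12C", "13C")
        }
        logger.info("stage gradient: %d fractions over [%.3f, %.3f] g/mL",
                    config.n_fractions, config.density_min, config.density_max)

        stage = "select"
        qpcr_profiles: list[QPCRProfile] = []
        normalized: dict[str, list[QPCRProfile]] = {"12C": [], "13C": []}
        targets = labeled_ids or [community[0].id]
        qpcr_rng = np.random.default_rng(seeds["qpcr"])
        for cond in ("12C", "13C"):
            for rep in range(1, config.replicates + 1):
                prof = sip_synth.simulate_qpcr_profile(
                    profiles[cond],
                    targets,
                    noise_cv=config.qpcr_noise_cv,
                    seed=int(qpcr_rng.integers(0, 2**31 - 1)),
                    replicate=str(rep),
                )
                qpcr_profiles.append(prof)
                normalized[cond].append(fraction_select.normalize_to_max(prof))
        grid = profiles["13C"].centers
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            ratios = fraction_select.enrichment_ratio(
                normalized["13C"], normalized["12C"], grid
            )
            selected = fraction_select.select_heavy_fractions(
                ratios,
                ratio_threshold=config.ratio_threshold,
                density_window=(config.select_window_lo, config.select_window_hi),
            )
        logger.info("stage select: %d fractions passed (threshold %.2f, window %.3f-%.3f)",
                    len(selected), config.ratio_threshold,
                    config.select_window_lo, config.select_window_hi)
        report["selection"] = {
            "ratio_threshold": config.ratio_threshold,
            "window_g_ml": [config.select_window_lo, config.select_window_hi],
            "selected_densities": [round(d, 6) for d in selected],
            "qpcr_targets": targets,
        }

        stage = "counts"
        design = sip_synth.SIPDesign(
            replicates=config.replicates,
            depth=config.depth,
            dispersion=config.dispersion,
            qpcr_targets=tuple(targets),
            seed=seeds["counts"],
            count_mode=config.count_mode,
        )
        matrix = sip_synth.simulate_counts(
            profiles["12C"],
            profiles["13C"],
            design,
            (config.heavy_window_lo, config.heavy_window_hi),
        )

        stage = "enrich"
        matrix.require_replication()
        sf = enrichment.size_factors(matrix.counts)
        disp = enrichment.estimate_dispersion(matrix.counts, sf, matrix.conditions)
        result = enrichment.wald_test(
            matrix.counts, sf, disp, matrix.conditions,
            alpha=config.alpha, use_bh=config.use_bh,
        )
        ranked = enrichment.rank_enriched(
            result, lfc_min=config.lfc_min, use_bh=config.use_bh, alpha=config.alpha
        )
        logger.info("stage enrich: %d features called 13C-enriched", len(ranked))
        report["enrichment"] = {
            "alpha": config.alpha,
            "use_bh": config.use_bh,
            "enriched_ranked": ranked,
            "n_tested": int(result["pvalue"].notna().sum()),
            "results": {
                str(fid): {
                    "baseMean": _round6(row["baseMean"]),
                    "log2FoldChange": _round6(row["log2FoldChange"]),
                    "pvalue": _round6(row["pvalue"]),
                    "padj": _round6(row["padj"]),
                    "enriched": bool(row["enriched"]),
                }
                for fid, row in result.iterrows()
            },
        }

        stage = "ani"
        if config.run_ani and labeled_ids:
            genome_rng = np.random.default_rng(seeds["genomes"])
            genomes, truth_pop = [], {}
            by_id = {p.id: p for p in community}
            for pid in labeled_ids:
                base = sip_synth.random_genome(
                    config.ani_genome_length, by_id[pid].gc, genome_rng
                )
                close = sip_synth.mutate_genome(base, 0.005, genome_rng)
                distant = sip_synth.mutate_genome(base, 0.08, genome_rng)
                genomes.extend(
                    [
                        genome_compare.GenomeSequence(pid, (base,)),
                        genome_compare.GenomeSequence(f"{pid}_variant", (close,)),
                        genome_compare.GenomeSequence(f"{pid}_relative", (distant,)),
                    ]
                )
                truth_pop[pid] = {"variant_of": pid}
            matrix_ani = genome_compare.ani_matrix(genomes)
            clust = genome_compare.ward_cluster(
                matrix_ani,
                population_cut=config.population_cut,
                species_cut=config.species_cut,
            )
            report["ani"] = {
                "ids": list(matrix_ani.ids),
                "ani_pct": [
                    [_round6(v) for v in row] for row in matrix_ani.ani.to_numpy()
                ],
                "populations": clust["populations"],
                "species": clust["species"],
                "newick": clust["newick"],
            }
        else:
            report["ani"] = None

        stage = "thermo"
        report["thermodynamics"] = _thermo_summary(config)
    except Exception as exc:
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out is not None:
        write_truth_tsv(community, out / "truth.tsv")
        write_qpcr_tsv(qpcr_profiles, out / "qpcr.tsv")
        write_counts_tsv(matrix, out / "counts.tsv")
        result.to_csv(out / "enrichment.tsv", sep="\t", index_label="feature")
        if report["ani"] is not None:
            matrix_ani.ani.to_csv(out / "ani.tsv", sep="\t", index_label="genome")
            (out / "dendrogram.nwk").write_text(report["ani"]["newick"] + "\n")
            write_fasta([(g.id, g.contigs[0]) for g in genomes], out / "genomes.fasta")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report


def _round6(value) -> float | None:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return None
    return float(f"{float(value):.6g}")
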
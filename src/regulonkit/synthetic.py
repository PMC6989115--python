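"""Ground-truthed synthetic data emulating the study design.

The generator stands in for the deposited sequencing data: a single
bacterial-style contig with non-overlapping genes, a planted regulon
(direct targets with a consensus binding site and ChIP peak upstream,
indirect targets with an expression effect but no nearby binding, null
genes), decoy peaks, negative-binomial counts for a 2 genotypes × 2
conditions × 3 replicates design, and qPCR Ct tables. Every random choice
flows from one seed through a fixed stream-splitting rule, so a dataset is
fully reproducible and every test can interrogate the ground truth.

Expression model (log2 scale):

    log2 mean_ij = log2 q_i + log2 s_j + β_i(cond_j) · [genotype_j = mutant]
                   + γ_i · [cond_j = limitation]

with gene baseline q_i, library size s_j, genotype effect β (the regulon
signal; negative = activated by the regulator, i.e. lower in the mutant)
and a genotype-independent condition effect γ. Counts are negative binomial
with constant dispersion φ (variance μ + φμ²; φ = 0 degenerates to
Poisson). One flagship gene carries the strongest activation in the study
(~238-fold lower in the mutant) and one null-role gene emulates the
concurrently condition-repressed transcript (~10-fold down on carbon
limitation in both genotypes, i.e. no regulon signal).

Only a minority of genes (24 of 120 by default, ~20%) carry a regulon
effect, mirroring the real study's proportions; a much larger affected
fraction would bias median-of-ratios normalization through library
composition, which is a property of the data, not of the estimator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    CountMatrix,
    Gene,
    GenomeAnnotation,
    Peak,
    SampleSheet,
    write_annotation,
    write_counts,
    write_fasta,
    write_peaks,
)
from .motif import DEFAULT_CONSENSUS, IUPAC_SETS, MotifConsensus

ROLES = ("direct_activated", "direct_repressed", "indirect", "null")

_STAGES = {"genome": 0, "roles": 1, "sites": 2, "peaks": 3, "counts": 4, "ct": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage.

    Streams are split with ``SeedSequence(seed, spawn_key=(stage index,))``
    so adding draws in one stage never perturbs another.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],))
    )


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study; defaults emulate the source design.

    120 genes on a 100-kb contig, 4 + 12 direct targets (the study's
    activated:repressed imbalance, scaled down), 8 indirect and 96 null
    genes; 5-fold regulon effects with one 238-fold flagship; NB dispersion
    0.05; 2 × 2 × 3 samples.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_genes: int = 120
    n_direct_activated: int = 4
    n_direct_repressed: int = 12
    n_indirect: int = 8
    n_null: int = 96
    effect_log2fc: float = math.log2(5)
    flagship_effect_log2fc: float = math.log2(238)
    condition_gene_log2fc: float = -math.log2(10)
    include_flagship: bool = True
    include_condition_gene: bool = True
    nb_dispersion: float = 0.05
    mean_expression_log10_range: tuple[float, float] = (2.7, 3.7)
    library_size_range: tuple[float, float] = (0.7, 1.4)
    n_replicates: int = 3
    n_decoy_peaks: int = 300
    peak_width_range: tuple[int, int] = (150, 300)
    summit_jitter: int = 10
    gene_length_range: tuple[int, int] = (400, 600)
    min_intergenic_gap: int = 200
    upstream_offset: int = 60
    ct_noise_sd: float = 0.2
    contig: str = "contig_1"

    def __post_init__(self) -> None:
        role_sum = (
            self.n_direct_activated + self.n_direct_repressed
            + self.n_indirect + self.n_null
        )
        if role_sum != self.n_genes:
            raise ValueError(
                f"role counts sum to {role_sum} but n_genes is {self.n_genes}"
            )
        for name in (
            "n_genes", "n_direct_activated", "n_direct_repressed",
            "n_indirect", "n_null", "n_decoy_peaks", "n_replicates",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be ≥ 0")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be ≥ 0")

    def null_model(self) -> "SimulationParams":
        """The same design with every planted effect removed (global null)."""
        return replace(
            self,
            n_direct_activated=0,
            n_direct_repressed=0,
            n_indirect=0,
            n_null=self.n_genes,
            include_flagship=False,
            include_condition_gene=False,
        )


@dataclass
class GroundTruth:
    """What was planted: per-gene roles and effects, sites, peak origins.

    ``genes`` is indexed by gene_id with columns role, is_flagship,
    beta_glucose / beta_limitation (genotype log2 effects per condition),
    gamma (condition log2 effect), site_start / site_end. ``peaks`` is
    indexed by peak_id with columns planted and gene_id.
    """

    genes: pd.DataFrame
    peaks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["planted", "gene_id"])
    )

    def gene_ids(self, *roles: str) -> list[str]:
        if not roles:
            return list(self.genes.index)
        return list(self.genes.index[self.genes["role"].isin(roles)])

    @property
    def direct_gene_ids(self) -> list[str]:
        return self.gene_ids("direct_activated", "direct_repressed")

    def expected_direction(self, gene_id: str) -> str | None:
        role = self.genes.at[gene_id, "role"]
        if role == "direct_activated":
            return "activated"
        if role == "direct_repressed":
            return "repressed"
        return None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes.reset_index().to_dict(orient="records"),
            "peaks": self.peaks.reset_index().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    params: SimulationParams, seed: int | None = None
) -> tuple[dict[str, str], GenomeAnnotation]:
    """Random contig with non-overlapping, alternating-strand genes.

    Genes are separated by intergenic gaps of at least
    ``min_intergenic_gap`` bp; leftover space is spread randomly over the
    gaps. Raises when the genes cannot fit.
    """
    rng = stage_rng(params.seed if seed is None else seed, "genome")
    n = params.n_genes
    lo, hi = params.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n) if n else np.array([], dtype=int)
    required = int(lengths.sum()) + (n + 1) * params.min_intergenic_gap
    if required > params.genome_length:
        raise ValueError(
            f"{n} genes need ≥{required} bp but genome_length is "
            f"{params.genome_length}; increase genome_length"
        )
    slack = params.genome_length - required
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1))) if n else [slack]
    genes: list[Gene] = []
    pos = 0
    for i in range(n):
        pos += params.min_intergenic_gap + int(extra[i])
        start = pos
        end = start + int(lengths[i])
        genes.append(
            Gene(
                gene_id=f"SYN{i + 1:04d}",
                contig=params.contig,
                start=start,
                end=end,
                strand="+" if i % 2 == 0 else "-",
            )
        )
        pos = end
    bases = np.array(list("ACGT"))
    sequence = "".join(bases[rng.integers(0, 4, size=params.genome_length)])
    annotation = GenomeAnnotation(
        genes, contig_lengths={params.contig: params.genome_length}
    )
    return {params.contig: sequence}, annotation


# ---------------------------------------------------------------------------
# roles


def assign_roles(
    annotation: GenomeAnnotation, params: SimulationParams, seed: int | None = None
) -> GroundTruth:
    """Partition genes into roles and set their planted log2 effects."""
    rng = stage_rng(params.seed if seed is None else seed, "roles")
    gene_ids = [g.gene_id for g in annotation]
    order = list(rng.permutation(len(gene_ids)))
    blocks = {
        "direct_activated": params.n_direct_activated,
        "direct_repressed": params.n_direct_repressed,
        "indirect": params.n_indirect,
        "null": params.n_null,
    }
    roles = pd.Series(index=pd.Index(gene_ids, name="gene_id"), dtype=object)
    cursor = 0
    for role, count in blocks.items():
        for k in order[cursor : cursor + count]:
            roles.iloc[k] = role
        cursor += count

    genes = pd.DataFrame(
        {
            "role": roles,
            "is_flagship": False,
            "beta_glucose": 0.0,
            "beta_limitation": 0.0,
            "gamma": 0.0,
            "site_start": pd.array([pd.NA] * len(gene_ids), dtype="Int64"),
            "site_end": pd.array([pd.NA] * len(gene_ids), dtype="Int64"),
        }
    )
    effect = params.effect_log2fc
    for gid in genes.index[genes["role"] == "direct_activated"]:
        genes.loc[gid, ["beta_glucose", "beta_limitation"]] = -effect
    for gid in genes.index[genes["role"] == "direct_repressed"]:
        genes.loc[gid, ["beta_glucose", "beta_limitation"]] = effect
    indirect_ids = list(genes.index[genes["role"] == "indirect"])
    signs = rng.choice([-1.0, 1.0], size=len(indirect_ids))
    for gid, sign in zip(indirect_ids, signs):
        genes.loc[gid, ["beta_glucose", "beta_limitation"]] = sign * effect

    activated = list(genes.index[genes["role"] == "direct_activated"])
    if params.include_flagship and activated:
        # the strongest activation in the study, as a plain (large) genotype effect
        flagship = activated[0]
        genes.at[flagship, "is_flagship"] = True
        genes.loc[flagship, ["beta_glucose", "beta_limitation"]] = (
            -params.flagship_effect_log2fc
        )
    nulls = list(genes.index[genes["role"] == "null"])
    if params.include_condition_gene and nulls:
        # condition-responsive but regulator-independent transcript
        genes.at[nulls[0], "gamma"] = params.condition_gene_log2fc
    return GroundTruth(genes=genes)


# ---------------------------------------------------------------------------
# binding sites


def plant_sites(
    sequences: Mapping[str, str],
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    params: SimulationParams,
    consensus: MotifConsensus | str = DEFAULT_CONSENSUS,
    seed: int | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write one concrete consensus instantiation upstream of each direct gene.

    Each degenerate symbol is resolved uniformly at random; the site sits
    ``upstream_offset`` bp upstream of the gene start on its coding strand
    (forward-strand sequence is planted either way — the consensus is a
    palindrome, so strand does not matter for recovery). Sequence length is
    unchanged; positions are recorded in the returned site table and in
    ``truth.genes``.
    """
    if isinstance(consensus, str):
        consensus = MotifConsensus(consensus)
    rng = stage_rng(params.seed if seed is None else seed, "sites")
    base_sets = [sorted(s) for s in consensus.base_sets()]
    k = len(consensus)
    mutable = {name: bytearray(seq, "ascii") for name, seq in sequences.items()}
    records = []
    for gene_id in truth.direct_gene_ids:
        gene = annotation.by_id(gene_id)
        if gene.strand == "+":
            end = gene.start - params.upstream_offset
            start = end - k
        else:
            start = gene.end + params.upstream_offset
            end = start + k
        contig_len = len(sequences[gene.contig])
        if start < 0 or end > contig_len:
            raise ValueError(
                f"gene {gene_id}: no room for a {k}-bp site upstream"
            )
        if annotation.overlapping(gene.contig, start, end):
            raise ValueError(
                f"gene {gene_id}: upstream site region [{start}, {end}) is not intergenic"
            )
        site = "".join(bases[rng.integers(0, len(bases))] for bases in base_sets)
        mutable[gene.contig][start:end] = site.encode("ascii")
        truth.genes.at[gene_id, "site_start"] = start
        truth.genes.at[gene_id, "site_end"] = end
        records.append(
            {
                "gene_id": gene_id,
                "contig": gene.contig,
                "start": start,
                "end": end,
                "sequence": site,
            }
        )
    sites = pd.DataFrame(records, columns=["gene_id", "contig", "start", "end", "sequence"])
    return {name: buf.decode("ascii") for name, buf in mutable.items()}, sites


# ---------------------------------------------------------------------------
# peaks


def simulate_peaks(
    sites: pd.DataFrame,
    params: SimulationParams,
    seed: int | None = None,
    exclude: Sequence[tuple[int, int]] = (),
) -> tuple[list[Peak], pd.DataFrame]:
    """One peak over every planted site, plus uniformly placed decoys.

    A planted peak is centred on its site (summit at the site centre ±
    ``summit_jitter`` bp). Decoys avoid a 500-bp zone around planted sites
    plus any extra ``exclude`` intervals — the full dataset generator
    passes the neighbourhoods of indirect genes there, so an "effect but no
    nearby binding" gene can never pick up a decoy by chance. Planted peaks
    draw enrichment scores stochastically above the decoys'. Returns the
    peaks (sorted by position) and a peak-truth table.
    """
    rng = stage_rng(params.seed if seed is None else seed, "peaks")
    lo, hi = params.peak_width_range
    raw: list[tuple[int, int, int, float, bool, str]] = []
    exclusion: list[tuple[int, int]] = [tuple(iv) for iv in exclude]
    for row in sites.itertuples(index=False):
        width = int(rng.integers(lo, hi + 1))
        center = int(row.start) + (int(row.end) - int(row.start)) // 2
        jitter = (
            int(rng.integers(-params.summit_jitter, params.summit_jitter + 1))
            if params.summit_jitter
            else 0
        )
        start = max(0, center - width // 2)
        end = start + width
        summit = min(max(center + jitter, start), end - 1)
        score = float(rng.uniform(8.0, 30.0))
        raw.append((start, end, summit, score, True, row.gene_id))
        exclusion.append((int(row.start) - 500, int(row.end) + 500))

    placed = 0
    attempts = 0
    while placed < params.n_decoy_peaks:
        attempts += 1
        if attempts > 100 * max(params.n_decoy_peaks, 1):
            raise RuntimeError("could not place decoy peaks outside planted windows")
        width = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, max(params.genome_length - width, 1)))
        end = start + width
        if any(start < xe and xs < end for xs, xe in exclusion):
            continue
        summit = start + int(rng.integers(0, width))
        score = float(rng.uniform(1.5, 8.0))
        raw.append((start, end, summit, score, False, ""))
        placed += 1

    raw.sort(key=lambda t: (t[0], t[1]))
    peaks: list[Peak] = []
    truth_rows = []
    for i, (start, end, summit, score, planted, gene_id) in enumerate(raw):
        peak_id = f"peak_{i + 1:04d}"
        peaks.append(
            Peak(
                peak_id=peak_id,
                contig=params.contig,
                start=start,
                end=end,
                summit_offset=summit - start,
                score=score,
                qvalue_neglog10=score,
            )
        )
        truth_rows.append({"peak_id": peak_id, "planted": planted, "gene_id": gene_id})
    truth = pd.DataFrame(truth_rows, columns=["peak_id", "planted", "gene_id"])
    if len(truth):
        truth = truth.set_index("peak_id")
    return peaks, truth


# ---------------------------------------------------------------------------
# counts


def design_samples(params: SimulationParams) -> pd.DataFrame:
    """The 2 genotypes × 2 conditions × n replicates sample sheet frame."""
    rows = []
    for genotype in SampleSheet.GENOTYPES:
        for condition in SampleSheet.CONDITIONS:
            for rep in range(1, params.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{genotype}_{condition}_{rep}",
                        "genotype": genotype,
                        "condition": condition,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    params: SimulationParams,
    seed: int | None = None,
) -> tuple[CountMatrix, SampleSheet]:
    """Negative-binomial counts for the full design.

    K_ij ~ NB(mean = s_j · q_i · 2^(β_i(cond_j)·mut_j + γ_i·lim_j),
    dispersion φ); φ = 0 gives Poisson. Baselines q_i are log10-uniform
    over ``mean_expression_log10_range``; library sizes s_j uniform over
    ``library_size_range``.
    """
    gene_ids = [g.gene_id for g in annotation]
    missing = set(gene_ids) - set(truth.genes.index)
    if missing:
        raise ValueError(f"ground truth missing genes: {sorted(missing)[:3]}")
    rng = stage_rng(params.seed if seed is None else seed, "counts")
    design = design_samples(params)
    n_genes, n_samples = len(gene_ids), len(design)

    q = 10.0 ** rng.uniform(*params.mean_expression_log10_range, size=n_genes)
    s = rng.uniform(*params.library_size_range, size=n_samples)

    genes = truth.genes.loc[gene_ids]
    beta_glu = genes["beta_glucose"].to_numpy(float)
    beta_lim = genes["beta_limitation"].to_numpy(float)
    gamma = genes["gamma"].to_numpy(float)
    is_mut = (design["genotype"] == "mutant").to_numpy()
    is_lim = (design["condition"] == "limitation").to_numpy()

    beta = np.where(is_lim[None, :], beta_lim[:, None], beta_glu[:, None])
    log2_mu = (
        np.log2(q)[:, None]
        + np.log2(s)[None, :]
        + beta * is_mut[None, :]
        + gamma[:, None] * is_lim[None, :]
    )
    mu = 2.0**log2_mu
    if params.nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / params.nb_dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    frame = pd.DataFrame(
        counts.astype("int64"), index=pd.Index(gene_ids, name="gene_id"),
        columns=design.index,
    )
    return CountMatrix(frame), SampleSheet(design)


# ---------------------------------------------------------------------------
# qPCR


def simulate_ct(
    quantities: pd.DataFrame,
    params: SimulationParams,
    seed: int | None = None,
    intercept: float = 30.0,
) -> pd.DataFrame:
    """Turn relative template abundances into a Ct table.

    Ct = intercept − log2(abundance) + Normal(0, ct_noise_sd), i.e. perfect
    doubling per cycle. ``quantities`` needs an ``abundance`` column plus
    the identifying columns (sample_id, target, and optionally fraction,
    dilution, replicate, which default to NA / 1 / 1).
    """
    if "abundance" not in quantities.columns:
        raise ValueError("quantities needs an 'abundance' column")
    if (quantities["abundance"] <= 0).any():
        raise ValueError("abundances must be positive")
    rng = stage_rng(params.seed if seed is None else seed, "ct")
    out = quantities.copy()
    noise = (
        rng.normal(0.0, params.ct_noise_sd, size=len(out))
        if params.ct_noise_sd > 0
        else np.zeros(len(out))
    )
    out["ct"] = intercept - np.log2(out["abundance"].to_numpy(float)) + noise
    for column, default in (("fraction", "NA"), ("dilution", 1.0), ("replicate", 1)):
        if column not in out.columns:
            out[column] = default
    return out.drop(columns=["abundance"])


# ---------------------------------------------------------------------------
# the full bundle


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, with its ground truth."""

    params: SimulationParams
    sequences: dict[str, str]
    annotation: GenomeAnnotation
    sites: pd.DataFrame
    peaks: list[Peak]
    counts: CountMatrix
    sheet: SampleSheet
    truth: GroundTruth


def simulate_dataset(
    params: SimulationParams, consensus: MotifConsensus | str = DEFAULT_CONSENSUS
) -> SyntheticDataset:
    """Run every generator stage under the stream-splitting rule."""
    sequences, annotation = simulate_genome(params)
    truth = assign_roles(annotation, params)
    sequences, sites = plant_sites(sequences, annotation, truth, params, consensus)
    indirect_windows = [
        (annotation.by_id(gid).start - 500, annotation.by_id(gid).end + 500)
        for gid in truth.gene_ids("indirect")
    ]
    peaks, peak_truth = simulate_peaks(sites, params, exclude=indirect_windows)
    truth.peaks = peak_truth
    counts, sheet = simulate_counts(annotation, truth, params)
    return SyntheticDataset(
        params=params,
        sequences=sequences,
        annotation=annotation,
        sites=sites,
        peaks=peaks,
        counts=counts,
        sheet=sheet,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the standard on-disk formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff3": outdir / "genes.gff3",
        "peaks": outdir / "peaks.narrowPeak",
        "counts": outdir / "counts.tsv",
        "sheet": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(dataset.sequences, paths["fasta"])
    write_annotation(dataset.annotation, paths["gff3"])
    write_peaks(dataset.peaks, paths["peaks"])
    write_counts(dataset.counts, dataset.sheet, paths["counts"], paths["sheet"])
    dataset.truth.to_json(paths["truth"])
    return paths
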
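"""Seeded generators for every input the analysis pipeline consumes.

Real inputs to this toolkit are tRNA gene annotations on a genome, dual-
luciferase plate reads, DNA dose-response tables, targeted-proteomics
abundance tables, and qPCR Ct tables.  None of those ship with the package;
instead each simulator here produces the corresponding input with known
ground truth (recorded in a sidecar ``truth`` object/JSON) so every stage
of the pipeline can be tested end to end.

Noise structure emulates the assays:

* plate reads — a per-well transfection-efficiency factor multiplies both
  luciferase channels (lognormal, so the suppression ratio is unaffected by
  construction), plus independent lognormal measurement noise per channel;
* dose-response ratios — multiplicative lognormal noise around the
  saturation model;
* MS abundances — per-residue ionization factors (lognormal across
  residues) distorting both the equimolar control and the sample, plus
  lognormal measurement noise;
* Ct values — additive Gaussian noise.

Every simulator is a pure function of its config and seed: the same seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import model_S
from .errors import InputError
from .fidelity_ms import AMINO_ACIDS
from .sequence import revcomp

DNA = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: canonical cloverleaf geometry used for simulated genes (73-nt gene body,
#: no encoded CCA): 7-bp acceptor, 4-bp D, 5-bp anticodon and 5-bp T stems.
CANONICAL_STRUCTURE = (
    "(((((((" + ".." + "((((" + "." * 8 + "))))" + "."
    + "(((((" + "." * 7 + ")))))" + "." * 5
    + "(((((" + "." * 7 + ")))))" + ")))))))" + "."
)
ANTICODON_INDICES = (33, 34, 35)


@dataclass
class SimConfig:
    """All ground-truth settings for the simulators.

    Defaults mirror the screening study's conditions where stated (six
    transfection replicates, ~10% plate read noise, saturating dose model)
    and realistic assay magnitudes elsewhere.
    """

    seed: int = 0
    # genome / gene annotation
    n_genes: int = 30
    flank_margin: int = 120  # intergenic room on each side of a gene, nt
    n_duplicate_flanks: int = 3
    uce5_length: int = 55
    trailer_length: int = 35
    n_chroms: int = 2
    # plate screen
    n_replicates: int = 6
    channel_cv: float = 0.10
    efficiency_sigma: float = 0.5  # lognormal sigma of per-well transfection
    n_controls_per_plate: int = 4
    nluc_base: float = 1e3
    fluc_base: float = 5e4
    # dose response
    true_sup_max: float = 40.0
    true_dd50: float = 8.0
    doses: tuple = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)
    dose_cv: float = 0.10
    dose_replicates: int = 6
    # targeted MS
    cognate_aa: str = "R"
    cognate_fraction: float = 0.98
    ionization_sigma: float = 0.5  # spread of per-residue ionization factors
    ms_cv: float = 0.05
    # qPCR
    ddct_truths: dict = field(default_factory=lambda: {
        "calibrator": 0.0, "optimized": -2.0, "medium": -1.0, "weak": 1.5})
    qpcr_calibrator: str = "calibrator"
    ct_sd: float = 0.10

    def __post_init__(self) -> None:
        for name in ("channel_cv", "efficiency_sigma", "dose_cv",
                     "ionization_sigma", "ms_cv", "ct_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")


def _lognormal_factor(rng: np.random.Generator, sigma: float,
                      size=None) -> np.ndarray:
    """exp(sigma * z - sigma^2 / 2): multiplicative noise with mean 1.

    Drawn via explicit standard normals so the stream consumption does not
    depend on sigma (setting sigma to 0 reuses the same draws).
    """
    z = rng.standard_normal(size=size)
    return np.exp(sigma * z - sigma ** 2 / 2.0)


def _cv_to_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv ** 2)))


# ---------------------------------------------------------------------------
# genome + gene annotation


def make_canonical_trna(rng: np.random.Generator,
                        anticodon: str = "TCT") -> tuple[str, str]:
    """A random 73-nt tRNA gene body with the canonical cloverleaf structure.

    Stems are Watson-Crick complementary; the anticodon triplet is placed at
    the center of the 7-nt anticodon loop (0-based indices 33-35).
    """
    def rand(n: int) -> str:
        return "".join(rng.choice(list(DNA), size=n))

    def stem(n: int) -> tuple[str, str]:
        five = rand(n)
        return five, "".join(COMP[b] for b in reversed(five))

    acc5, acc3 = stem(7)
    d5, d3 = stem(4)
    ac5, ac3 = stem(5)
    t5, t3 = stem(5)
    ac_loop = rand(2) + anticodon.upper() + rand(2)
    body = (acc5 + rand(2) + d5 + rand(8) + d3 + rand(1)
            + ac5 + ac_loop + ac3 + rand(5)
            + t5 + rand(7) + t3 + acc3 + rand(1))
    assert len(body) == len(CANONICAL_STRUCTURE) == 73
    return body, CANONICAL_STRUCTURE


@dataclass
class SimulatedGenome:
    """A toy genome with planted tRNA genes and their ground truth."""

    chromosomes: dict[str, str]
    bed: pd.DataFrame
    structures: dict[str, str]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        with fasta.open("w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k:k + 70] + "\n")
        bed = outdir / "genes.bed"
        self.bed.to_csv(bed, sep="\t", header=False, index=False)
        structures = outdir / "structures.tsv"
        with structures.open("w") as fh:
            for gene_id, struct in self.structures.items():
                fh.write(f"{gene_id}\t{struct}\n")
        truth = outdir / "genome_truth.json"
        truth.write_text(json.dumps(self.truth, indent=1))
        return {"fasta": fasta, "bed": bed, "structures": structures,
                "truth": truth}


ISOTYPE_ANTICODONS = [("Arg", "TCT"), ("Leu", "CAA"), ("Gly", "GCC"),
                      ("Trp", "CCA"), ("Tyr", "GTA"), ("Cys", "GCA")]


def sim_genome(cfg: SimConfig) -> SimulatedGenome:
    """Plant tRNA genes on both strands of a random genome.

    The first ``n_duplicate_flanks`` genes after the first share the first
    gene's 5' flank (in transcriptional sense), giving a known number of
    exact duplicates for deduplication tests.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_len = 73
    margin = cfg.flank_margin
    if margin < max(cfg.uce5_length, cfg.trailer_length):
        raise InputError("flank_margin shorter than requested flank lengths")
    slot = gene_len + 2 * margin
    per_chrom = -(-cfg.n_genes // cfg.n_chroms)
    chrom_len = per_chrom * slot + margin
    chromosomes = {
        f"chr{c + 1}": list("".join(rng.choice(list(DNA), size=chrom_len)))
        for c in range(cfg.n_chroms)
    }

    genes = []
    bed_rows = []
    structures: dict[str, str] = {}
    for g in range(cfg.n_genes):
        chrom = f"chr{g % cfg.n_chroms + 1}"
        slot_idx = g // cfg.n_chroms
        start = margin + slot_idx * slot
        end = start + gene_len
        strand = "+" if rng.random() < 0.5 else "-"
        isotype, anticodon = ISOTYPE_ANTICODONS[g % len(ISOTYPE_ANTICODONS)]
        body, structure = make_canonical_trna(rng, anticodon=anticodon)
        gene_id = f"tRNA-{isotype}-{anticodon}-{g + 1}-1"
        seq = chromosomes[chrom]
        planted = body if strand == "+" else revcomp(body)
        seq[start:end] = list(planted)
        genes.append({
            "gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
            "strand": strand, "body": body, "anticodon": anticodon,
            "isotype": isotype,
        })
        bed_rows.append([chrom, start, end, gene_id, 0, strand])
        structures[gene_id] = structure

    # engineer duplicate 5' flanks: genes 1..n share gene 0's flank sequence
    def write_flank5(gene: dict, flank: str) -> None:
        seq = chromosomes[gene["chrom"]]
        if gene["strand"] == "+":
            seq[gene["start"] - len(flank):gene["start"]] = list(flank)
        else:
            seq[gene["end"]:gene["end"] + len(flank)] = list(revcomp(flank))

    def read_flank(gene: dict, side: int, length: int) -> str:
        seq = chromosomes[gene["chrom"]]
        upstream = (side == 5) == (gene["strand"] == "+")
        if upstream:
            window = seq[gene["start"] - length:gene["start"]]
        else:
            window = seq[gene["end"]:gene["end"] + length]
        flank = "".join(window)
        return flank if gene["strand"] == "+" else revcomp(flank)

    n_dup = min(cfg.n_duplicate_flanks, cfg.n_genes - 1)
    if n_dup > 0:
        master = read_flank(genes[0], 5, cfg.uce5_length)
        for gene in genes[1:1 + n_dup]:
            write_flank5(gene, master)

    for gene in genes:
        gene["flank5"] = read_flank(gene, 5, cfg.uce5_length)
        gene["flank3"] = read_flank(gene, 3, cfg.trailer_length)

    chrom_strings = {k: "".join(v) for k, v in chromosomes.items()}
    truth = {
        "n_genes": cfg.n_genes,
        "n_duplicate_flanks": n_dup,
        "expected_unique_flank5": cfg.n_genes - n_dup,
        "genes": genes,
    }
    bed = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name",
                                          "score", "strand"])
    return SimulatedGenome(chromosomes=chrom_strings, bed=bed,
                           structures=structures, truth=truth)


# ---------------------------------------------------------------------------
# plate screen


def sim_plates(cfg: SimConfig, true_ratios: dict[str, float],
               seed: int | None = None) -> pd.DataFrame:
    """Simulated dual-luciferase wells for the given members.

    One plate per replicate (members spill onto extra plates past 96 wells);
    each plate carries ``n_controls_per_plate`` no-tRNA wells with true
    ratio 1.  The per-well efficiency factor and the per-channel noise are
    drawn from separate seeded streams, so regenerating with a different
    ``efficiency_sigma`` but the same seed reuses identical channel noise.
    """
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    rng_channel, rng_eff = [np.random.default_rng(s) for s in ss.spawn(2)]
    sigma_ch = _cv_to_sigma(cfg.channel_cv)
    wells_per_plate = 96
    member_ids = list(true_ratios)
    capacity = wells_per_plate - cfg.n_controls_per_plate
    rows = []
    well_names = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    for rep in range(1, cfg.n_replicates + 1):
        for chunk_idx in range(-(-len(member_ids) // capacity)):
            chunk = member_ids[chunk_idx * capacity:(chunk_idx + 1) * capacity]
            plate_id = f"rep{rep}_p{chunk_idx + 1}"
            layout = ([(NO_TRNA_ID, 1.0)] * cfg.n_controls_per_plate
                      + [(m, true_ratios[m]) for m in chunk])
            for w, (member_id, ratio) in enumerate(layout):
                eff = float(_lognormal_factor(rng_eff, cfg.efficiency_sigma))
                noise_n = float(_lognormal_factor(rng_channel, sigma_ch))
                noise_f = float(_lognormal_factor(rng_channel, sigma_ch))
                rows.append({
                    "plate_id": plate_id, "well": well_names[w],
                    "member_id": member_id,
                    "nluc": cfg.nluc_base * ratio * eff * noise_n,
                    "fluc": cfg.fluc_base * eff * noise_f,
                    "cell_line": "sim16HBE", "replicate": rep,
                })
    return pd.DataFrame(rows)


NO_TRNA_ID = "no_tRNA"


# ---------------------------------------------------------------------------
# dose response


def sim_dose(cfg: SimConfig, seed: int | None = None,
             ) -> tuple[pd.DataFrame, dict]:
    """Dose-response table drawn from the saturation model plus noise."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sigma = _cv_to_sigma(cfg.dose_cv)
    rows = []
    for rep in range(1, cfg.dose_replicates + 1):
        for dose in cfg.doses:
            expected = model_S(dose, cfg.true_sup_max, cfg.true_dd50)
            noise = float(_lognormal_factor(rng, sigma))
            rows.append({"member_id": "sim_cassette", "dose_ng_ul": dose,
                         "ratio": expected * noise, "replicate": rep})
    truth = {"sup_max": cfg.true_sup_max, "dd50": cfg.true_dd50,
             "cv": cfg.dose_cv, "replicates": cfg.dose_replicates}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# targeted MS


def sim_ms(cfg: SimConfig, seed: int | None = None,
           ) -> tuple[pd.Series, pd.Series, dict]:
    """(control, sample) per-residue abundances with known truth.

    The control emulates the equimolar 20-protein mix: abundance is the
    residue's ionization factor (times noise).  The sample's abundance is
    the true incorporation fraction times the same factor (times noise), so
    ionization reweighting should recover the fractions.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    aas = list(AMINO_ACIDS)
    if cfg.cognate_aa not in aas:
        raise InputError(f"cognate_aa {cfg.cognate_aa!r} is not an amino acid")
    fractions = pd.Series(
        (1.0 - cfg.cognate_fraction) / (len(aas) - 1), index=aas)
    fractions[cfg.cognate_aa] = cfg.cognate_fraction
    factors = pd.Series(
        np.exp(cfg.ionization_sigma * rng.standard_normal(len(aas))),
        index=aas)
    sigma = _cv_to_sigma(cfg.ms_cv)
    scale = 1e6
    control = scale * factors * _lognormal_factor(rng, sigma, size=len(aas))
    sample = (scale * fractions * factors
              * _lognormal_factor(rng, sigma, size=len(aas)))
    truth = {"fractions": fractions.to_dict(),
             "ionization_factors": factors.to_dict(),
             "cognate_aa": cfg.cognate_aa, "cv": cfg.ms_cv}
    return control, sample, truth


# ---------------------------------------------------------------------------
# qPCR


def sim_qpcr(cfg: SimConfig, seed: int | None = None,
             n_triplicate: int = 3) -> tuple[pd.DataFrame, dict]:
    """Long-format Ct table realising the configured ddCt truths."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ref_mean, target_base = 20.0, 24.0
    rows = []
    for sample_id, ddct in cfg.ddct_truths.items():
        for _ in range(n_triplicate):
            rows.append({"sample_id": sample_id, "target": "TBP",
                         "ct": ref_mean + cfg.ct_sd * rng.standard_normal()})
        for _ in range(n_triplicate):
            rows.append({"sample_id": sample_id, "target": "TTT",
                         "ct": (target_base + ddct
                                + cfg.ct_sd * rng.standard_normal())})
    truth = {"ddct": dict(cfg.ddct_truths),
             "rq": {k: 2.0 ** -v for k, v in cfg.ddct_truths.items()},
             "calibrator": cfg.qpcr_calibrator}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# one-stop fixture writer


def sim_all(cfg: SimConfig, outdir: str | Path) -> dict:
    """Write every simulated input plus a combined truth JSON to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = sim_genome(cfg)
    paths = genome.write(outdir)

    ratio_rng = np.random.default_rng(cfg.seed + 1)
    true_ratios = {
        f"member_{k:03d}": float(r)
        for k, r in enumerate(10.0 ** ratio_rng.uniform(-0.5, 2.0, size=24))
    }
    plates = sim_plates(cfg, true_ratios)
    plates.to_csv(outdir / "plates.csv", index=False)

    dose_df, dose_truth = sim_dose(cfg)
    dose_df.to_csv(outdir / "dose.csv", index=False)

    control, sample, ms_truth = sim_ms(cfg)
    control.rename_axis("aa").rename("abundance").to_csv(
        outdir / "ms_control.csv")
    sample.rename_axis("aa").rename("abundance").to_csv(
        outdir / "ms_sample.csv")

    ct_df, qpcr_truth = sim_qpcr(cfg)
    ct_df.to_csv(outdir / "qpcr.csv", index=False)

    truth = {
        "config": asdict(cfg),
        "plate_true_ratios": true_ratios,
        "dose": dose_truth,
        "ms": ms_truth,
        "qpcr": qpcr_truth,
        "genome": {k: v for k, v in genome.truth.items() if k != "genes"},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return {"paths": paths, "truth": truth}
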
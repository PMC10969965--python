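"""Synthetic genotyping-by-sequencing datasets with known sex linkage.

The generator emulates the marker-level signal that sex-linked locus
discovery exploits in species with homomorphic sex chromosomes and a
2n = 26 karyotype (13 chromosome pairs):

* non-recombining sex-linked SNPs follow a fixed-difference model — the
  homogametic sex is a/a and the heterogametic sex a/b, where b is the
  sex-limited (Y or W) allele.  Each such locus carries a haplotype
  label (b1 or b2) identifying which Y-haplotype variant it tags; the
  label is invisible in the genotype calls and exists so that Y-haplotype
  sharing between populations is measurable at desk scale;
* a configurable fraction r of sex-linked loci "behaves autosomally"
  (pseudoautosomal recombination), drawn from Hardy-Weinberg proportions
  while still residing on the sex chromosome;
* autosomal SNPs are Hardy-Weinberg draws with per-locus allele
  frequencies uniform over a minor-allele-frequency range;
* dominant presence/absence markers are present exactly in genotypically
  heterogametic individuals (sex-linked) or with a per-locus presence
  probability uniform on (0.3, 0.9) (autosomal);
* phenotypic sex flips with probability s per individual (sex reversal),
  each call is corrupted with probability e (replaced by a uniformly
  chosen different non-missing state) and dropped to missing with
  probability m;
* every locus receives a tag copied verbatim from its true chromosome of
  a freshly simulated random reference, so the mapping stage can recover
  the chromosome of origin.

Everything is reproducible: identical (config, seed) pairs yield
identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as slio
from .model import GenotypeMatrix, PAMatrix, Reference, Sex

__all__ = [
    "ScenarioConfig",
    "TruthTable",
    "SimulatedDataset",
    "generate_reference",
    "simulate_population",
    "simulate_introgression",
    "shared_y_allele_fraction",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulated population.

    Defaults describe a sib-ship-sized sample (10 males, 10 females) of
    an XY species with 13 chromosomes, 50 sex-linked and 2000 autosomal
    SNPs, 2% genotyping error, 10% missingness and 10% pseudoautosomal
    recombination among sex-linked loci.
    """

    n_males: int = 10
    n_females: int = 10
    system: str = "XY"                 # XY: males heterogametic; ZW: females
    sex_chrom: str = "chr7"
    n_chrom: int = 13
    chrom_length: int = 10_000
    n_snp_autosomal: int = 2000
    n_snp_sexlinked: int = 50
    n_pa_autosomal: int = 200
    n_pa_sexlinked: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    error_rate: float = 0.02
    missing_rate: float = 0.10
    recomb_fraction: float = 0.10
    sex_reversal: float = 0.0
    tag_length: int = 69
    seed: int = 0

    def __post_init__(self) -> None:
        if self.system not in ("XY", "ZW"):
            raise ValueError("system must be 'XY' or 'ZW'")
        if self.n_chrom < 2:
            raise ValueError("need at least 2 chromosomes")
        if self.sex_chrom not in self.chrom_ids():
            raise ValueError(
                f"sex_chrom {self.sex_chrom!r} not among {self.n_chrom} chromosomes"
            )
        if self.tag_length > self.chrom_length:
            raise ValueError("tag_length must not exceed chrom_length")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be contained in (0, 0.5]")
        for name in ("error_rate", "missing_rate", "recomb_fraction",
                     "sex_reversal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    def chrom_ids(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chrom + 1)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


TRUTH_COLUMNS = ["locus_id", "marker_class", "truth_class", "chromosome",
                 "position", "y_allele_label"]


@dataclass
class TruthTable:
    """Per-locus ground truth of a simulated dataset.

    ``truth_class`` is autosomal / sexlinked_nonrecombining /
    sexlinked_recombining; ``y_allele_label`` (b1/b2) is set for every
    sex-linked SNP locus and empty otherwise; ``position`` is the
    0-based tag start on ``chromosome``.
    """

    frame: pd.DataFrame

    def class_counts(self) -> dict[tuple[str, str], int]:
        return self.frame.groupby(["marker_class", "truth_class"]).size().to_dict()

    def ids(self, marker_class: str | None = None,
            truth_class: str | None = None) -> list[str]:
        f = self.frame
        if marker_class is not None:
            f = f[f["marker_class"] == marker_class]
        if truth_class is not None:
            f = f[f["truth_class"] == truth_class]
        return list(f["locus_id"])

    def sexlinked_ids(self, marker_class: str | None = None,
                      nonrecombining_only: bool = False) -> list[str]:
        f = self.frame[self.frame["truth_class"].str.startswith("sexlinked")]
        if nonrecombining_only:
            f = f[f["truth_class"] == "sexlinked_nonrecombining"]
        if marker_class is not None:
            f = f[f["marker_class"] == marker_class]
        return list(f["locus_id"])

    def y_labels(self) -> list[str]:
        """Y-haplotype labels of the sex-linked SNP block, in locus order."""
        f = self.frame
        sl = f[(f["marker_class"] == "SNP")
               & f["truth_class"].str.startswith("sexlinked")]
        return list(sl["y_allele_label"])


@dataclass
class SimulatedDataset:
    snp: GenotypeMatrix
    pa: PAMatrix
    reference: Reference
    truth: TruthTable
    config: ScenarioConfig
    genotypic_sexes: list[Sex]
    seed: Optional[int] = None


def generate_reference(config: ScenarioConfig, seed=None) -> Reference:
    """Simulate a reference genome of i.i.d. uniform bases."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sequences = {}
    for cid in config.chrom_ids():
        sequences[cid] = "".join(
            _BASES[rng.integers(0, 4, size=config.chrom_length)]
        )
    return Reference(chrom_ids=config.chrom_ids(), sequences=sequences)


def _inject_noise(rng, calls: np.ndarray, n_states: int, e: float, m: float):
    """Per-call error (different non-missing state) then missingness."""
    if e > 0:
        err = rng.random(calls.shape) < e
        shift = rng.integers(1, n_states, size=calls.shape)
        calls[err] = (calls[err] + shift[err]) % n_states
    if m > 0:
        calls[rng.random(calls.shape) < m] = -1
    return calls


def simulate_population(
    config: ScenarioConfig,
    reference: Reference | None = None,
    seed=None,
) -> SimulatedDataset:
    """Simulate one population's SNP and presence/absence matrices.

    ``seed`` (an int or numpy SeedSequence) overrides ``config.seed``.
    The reference, when not supplied, is generated from the same random
    stream's configuration seed.
    """
    base_seed = config.seed if seed is None else seed
    if reference is None:
        reference = generate_reference(config, seed=base_seed)
    if (reference.chrom_ids != config.chrom_ids()
            or any(len(reference.sequences[c]) != config.chrom_length
                   for c in reference.chrom_ids)):
        raise ValueError("reference is inconsistent with the scenario config")
    rng = np.random.default_rng(base_seed)

    n = config.n_males + config.n_females
    individual_ids = [f"ind{i + 1:03d}" for i in range(n)]
    # genotypic heterogamety: XY -> the n_males genotypic males; ZW -> females
    genotypic_male = np.zeros(n, dtype=bool)
    genotypic_male[: config.n_males] = True
    heterogametic = genotypic_male if config.system == "XY" else ~genotypic_male
    genotypic_sexes = [Sex.MALE if gm else Sex.FEMALE for gm in genotypic_male]
    # phenotypic sex: genotypic sex, flipped with probability sex_reversal
    flip = rng.random(n) < config.sex_reversal
    phenotypic = [
        (Sex.FEMALE if gm else Sex.MALE) if fl else (Sex.MALE if gm else Sex.FEMALE)
        for gm, fl in zip(genotypic_male, flip)
    ]

    lo, hi = config.maf_range
    autosomes = [c for c in config.chrom_ids() if c != config.sex_chrom]

    def hw_genotypes(n_loci: int) -> np.ndarray:
        p = rng.uniform(lo, hi, size=n_loci)
        return rng.binomial(2, p[:, None], size=(n_loci, n)).astype(np.int8)

    def pick_recombining(n_loci: int) -> np.ndarray:
        n_rec = int(round(config.recomb_fraction * n_loci))
        mask = np.zeros(n_loci, dtype=bool)
        if n_rec:
            mask[rng.choice(n_loci, size=n_rec, replace=False)] = True
        return mask

    # ---- SNP loci --------------------------------------------------------
    n_sl, n_au = config.n_snp_sexlinked, config.n_snp_autosomal
    sl_recomb = pick_recombining(n_sl)
    y_labels = np.where(rng.random(n_sl) < 0.5, "b1", "b2")
    snp_sl = np.where(heterogametic[None, :], 1, 0).repeat(n_sl, axis=0) \
        if n_sl else np.zeros((0, n), dtype=np.int8)
    snp_sl = snp_sl.astype(np.int8)
    if sl_recomb.any():
        snp_sl[sl_recomb] = hw_genotypes(int(sl_recomb.sum()))
    snp_au = hw_genotypes(n_au)

    # ---- presence/absence loci ------------------------------------------
    n_pa_sl, n_pa_au = config.n_pa_sexlinked, config.n_pa_autosomal
    pa_sl_recomb = pick_recombining(n_pa_sl)
    pa_sl = np.where(heterogametic[None, :], 1, 0).repeat(n_pa_sl, axis=0) \
        if n_pa_sl else np.zeros((0, n), dtype=np.int8)
    pa_sl = pa_sl.astype(np.int8)
    if pa_sl_recomb.any():
        q = rng.uniform(0.3, 0.9, size=int(pa_sl_recomb.sum()))
        pa_sl[pa_sl_recomb] = (rng.random((int(pa_sl_recomb.sum()), n))
                               < q[:, None]).astype(np.int8)
    q_au = rng.uniform(0.3, 0.9, size=n_pa_au)
    pa_au = (rng.random((n_pa_au, n)) < q_au[:, None]).astype(np.int8)

    # ---- chromosome of origin and tags ----------------------------------
    def locus_block(prefix, n_loci, sexlinked, recomb_mask):
        ids = [f"{prefix}{i + 1:05d}" for i in range(n_loci)]
        if sexlinked:
            chroms = [config.sex_chrom] * n_loci
            classes = np.where(recomb_mask, "sexlinked_recombining",
                               "sexlinked_nonrecombining")
        else:
            chroms = list(rng.choice(autosomes, size=n_loci))
            classes = np.full(n_loci, "autosomal")
        positions = rng.integers(
            0, config.chrom_length - config.tag_length + 1, size=n_loci
        )
        tags = [reference.sequences[c][p : p + config.tag_length]
                for c, p in zip(chroms, positions)]
        return ids, chroms, list(classes), list(positions), tags

    snp_sl_ids, snp_sl_chr, snp_sl_cls, snp_sl_pos, snp_sl_tags = locus_block(
        "SNP_SL_", n_sl, True, sl_recomb)
    snp_au_ids, snp_au_chr, snp_au_cls, snp_au_pos, snp_au_tags = locus_block(
        "SNP_AU_", n_au, False, None)
    pa_sl_ids, pa_sl_chr, pa_sl_cls, pa_sl_pos, pa_sl_tags = locus_block(
        "PA_SL_", n_pa_sl, True, pa_sl_recomb)
    pa_au_ids, pa_au_chr, pa_au_cls, pa_au_pos, pa_au_tags = locus_block(
        "PA_AU_", n_pa_au, False, None)

    # ---- noise -----------------------------------------------------------
    snp_calls = np.vstack([snp_sl, snp_au]) if (n_sl + n_au) else \
        np.zeros((0, n), dtype=np.int8)
    pa_calls = np.vstack([pa_sl, pa_au]) if (n_pa_sl + n_pa_au) else \
        np.zeros((0, n), dtype=np.int8)
    snp_calls = _inject_noise(rng, snp_calls, 3,
                              config.error_rate, config.missing_rate)
    pa_calls = _inject_noise(rng, pa_calls, 2,
                             config.error_rate, config.missing_rate)

    snp = GenotypeMatrix(
        locus_ids=snp_sl_ids + snp_au_ids,
        individual_ids=individual_ids,
        sexes=list(phenotypic),
        calls=snp_calls,
        tags=snp_sl_tags + snp_au_tags,
    )
    pa = PAMatrix(
        locus_ids=pa_sl_ids + pa_au_ids,
        individual_ids=individual_ids,
        sexes=list(phenotypic),
        calls=pa_calls,
        tags=pa_sl_tags + pa_au_tags,
    )
    truth = TruthTable(frame=pd.DataFrame({
        "locus_id": snp_sl_ids + snp_au_ids + pa_sl_ids + pa_au_ids,
        "marker_class": ["SNP"] * (n_sl + n_au) + ["PA"] * (n_pa_sl + n_pa_au),
        "truth_class": snp_sl_cls + snp_au_cls + pa_sl_cls + pa_au_cls,
        "chromosome": snp_sl_chr + snp_au_chr + pa_sl_chr + pa_au_chr,
        "position": snp_sl_pos + snp_au_pos + pa_sl_pos + pa_au_pos,
        "y_allele_label": (list(y_labels) + [""] * n_au
                           + [""] * (n_pa_sl + n_pa_au)),
    }, columns=TRUTH_COLUMNS))
    return SimulatedDataset(
        snp=snp, pa=pa, reference=reference, truth=truth, config=config,
        genotypic_sexes=genotypic_sexes,
        seed=base_seed if isinstance(base_seed, (int, np.integer)) else None,
    )


_SHARED_FIELDS = ("n_snp_sexlinked", "system", "sex_chrom", "n_chrom",
                  "chrom_length", "tag_length")


def simulate_introgression(
    donor_config: ScenarioConfig,
    recipient_config: ScenarioConfig,
    control_config: ScenarioConfig,
    seed: int = 0,
) -> tuple[SimulatedDataset, SimulatedDataset, SimulatedDataset]:
    """Simulate a Y-haplotype introgression trio on a shared reference.

    The recipient population carries the donor's Y haplotype: its
    sex-linked SNP loci copy the donor's per-locus Y-allele labels
    exactly, while autosomal allele frequencies of all three populations
    are drawn independently.  The control draws its own Y labels.
    """
    for other, name in ((recipient_config, "recipient"),
                        (control_config, "control")):
        for f in _SHARED_FIELDS:
            if getattr(donor_config, f) != getattr(other, f):
                raise ValueError(
                    f"{name} config differs from donor in shared field {f!r}"
                )
    ss = np.random.SeedSequence(seed)
    ref_ss, donor_ss, recip_ss, ctrl_ss = ss.spawn(4)
    reference = generate_reference(donor_config, seed=ref_ss)
    donor = simulate_population(donor_config, reference, seed=donor_ss)
    recipient = simulate_population(recipient_config, reference, seed=recip_ss)
    control = simulate_population(control_config, reference, seed=ctrl_ss)
    # transplant the donor Y haplotype: identical labels, locus for locus
    sl_mask = ((recipient.truth.frame["marker_class"] == "SNP")
               & recipient.truth.frame["truth_class"].str.startswith("sexlinked"))
    recipient.truth.frame.loc[sl_mask, "y_allele_label"] = donor.truth.y_labels()
    return donor, recipient, control


def shared_y_allele_fraction(
    dataset_a: SimulatedDataset,
    dataset_b: SimulatedDataset,
    labels_a: Sequence[str] | None = None,
    labels_b: Sequence[str] | None = None,
) -> float:
    """Fraction of sex-linked SNP loci carrying the same Y-allele label.

    Loci are matched positionally within each dataset's sex-linked SNP
    block.  By default the truth labels are compared; externally
    inferred label sequences (e.g. sex-limited alleles recovered by the
    false-positive machinery on real data) can be supplied instead.
    """
    la = list(labels_a) if labels_a is not None else dataset_a.truth.y_labels()
    lb = list(labels_b) if labels_b is not None else dataset_b.truth.y_labels()
    n = min(len(la), len(lb))
    if n == 0:
        raise ValueError("no sex-linked SNP loci in common")
    return sum(1 for x, y in zip(la[:n], lb[:n]) if x == y) / n


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Serialise a simulated dataset to plain-text files in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "snp": out / "snp.csv",
        "pa": out / "pa.csv",
        "sex": out / "sex.csv",
        "tags": out / "tags.fasta",
        "reference": out / "reference.fasta",
        "truth": out / "truth.csv",
        "scenario": out / "scenario.json",
    }
    slio.write_genotype_table(dataset.snp, paths["snp"])
    slio.write_pa_table(dataset.pa, paths["pa"])
    slio.write_sex_file(dataset.snp, paths["sex"])
    tags = {**dataset.snp.tag_map(), **dataset.pa.tag_map()}
    slio.write_fasta(tags, paths["tags"])
    slio.write_fasta(dataset.reference, paths["reference"])
    dataset.truth.frame.to_csv(paths["truth"], index=False)
    echo = {"config": dataset.config.to_dict(), "seed": dataset.seed}
    paths["scenario"].write_text(json.dumps(echo, indent=2) + "\n")
    return paths
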
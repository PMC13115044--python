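"""Synthetic pooled-screen generator with ground truth.

Emulates the study design of a barcoded insertional-mutagenesis cold
screen: a mutant pool (CK1) is grown under control conditions to give
CK2, grown at 10 °C to give S10, and S10 is recovered under control
conditions to give S10R.  Each mutant carries one cassette insertion with
one unique barcode.  Per-mutant relative abundance evolves under a
multiplicative fitness model — a mutant with relative fitness ``f`` over
``g`` population doublings multiplies by ``2**(f*g)`` before
renormalisation — and each sample is then sequenced by drawing
``depth_per_sample`` reads multinomially.

Three mutant classes model the screen's biology: *cold-sensitive*
mutants (normal growth at room temperature, strongly impaired at 10 °C —
the depleted, "group 2" phenotype), *constitutive* growth-defect mutants
(impaired at room temperature, relatively rescued in cold — "group 1"),
and neutral mutants.  Class fractions, fitness ranges and doubling
numbers are configurable; every mutant's locus, fitnesses and expected
classification are recorded in a truth table so downstream recovery can
be tested exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from coldscreen import annotate as _annot
from coldscreen import screen as _screen
from coldscreen.barcodes import (
    DEFAULT_DOWNSTREAM_ANCHOR,
    DEFAULT_UPSTREAM_ANCHOR,
    CassetteSpec,
)
from coldscreen.mapping import revcomp

SAMPLES = (_screen.CK1, _screen.CK2, _screen.S10, _screen.S10R)
LEAP_SAMPLES = (_screen.CK1, _screen.S10R)  # samples used for locus mapping

# gene-geometry bounds used by the reference generator (bp)
_EXON_LEN = (200, 400)
_INTRON_LEN = (100, 300)
_N_EXONS = (2, 4)
_UTR_LEN = (60, 150)
_MIN_GAP = 1500  # leaves room for promoter windows and intergenic space
_CHROM_MARGIN = 200

_MAX_GENE_SPAN = _N_EXONS[1] * _EXON_LEN[1] + (_N_EXONS[1] - 1) * _INTRON_LEN[1]

# constant cassette-backbone filler appended after the downstream anchor
_BACKBONE = "CCTGTTATCCCTAGCGTAACGATCTCGTAGGATCCACTAGTTCTAGAGCGGCC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfigError(ValueError):
    """Invalid or infeasible simulation configuration."""


def _default_fitness_ranges() -> dict:
    return {
        # class: ((f_ctrl low, high), (f_cold low, high)); fitness 1 = neutral
        "neutral": ((1.0, 1.0), (1.0, 1.0)),
        "cold_sensitive": ((0.9, 1.0), (0.05, 0.3)),
        "constitutive": ((0.05, 0.3), (0.9, 1.0)),
    }


@dataclass
class SimConfig:
    """Study-design parameters of one synthetic screen."""

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 100_000
    n_genes: int = 30
    n_mutants: int = 500
    barcode_len: int = 22
    frac_cold_sensitive: float = 0.05
    frac_constitutive: float = 0.05
    fitness_ranges: dict = field(default_factory=_default_fitness_ranges)
    g_ctrl: float = 6.0  # doublings CK1 -> CK2 (two serial dilutions regrown)
    g_cold: float = 6.0  # doublings CK1 -> S10 (4 days at 10 degC)
    g_rec: float = 6.0   # doublings S10 -> S10R (two recovery cultures)
    depth_per_sample: int = 200_000
    flank_len: int = 60
    subst_error_rate: float = 0.002
    read_len: int = 75
    upstream_anchor: str = DEFAULT_UPSTREAM_ANCHOR
    downstream_anchor: str = DEFAULT_DOWNSTREAM_ANCHOR

    def __post_init__(self) -> None:
        for name in ("frac_cold_sensitive", "frac_constitutive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0,1], got {v}")
        if self.frac_cold_sensitive + self.frac_constitutive > 1.0:
            raise SimConfigError("class fractions sum to more than 1")
        if self.barcode_len < 8:
            raise SimConfigError(f"barcode_len must be >= 8, got {self.barcode_len}")
        if self.depth_per_sample < 1:
            raise SimConfigError("depth_per_sample must be >= 1")
        if self.n_chrom < 1 or self.n_genes < 1 or self.n_mutants < 1:
            raise SimConfigError("n_chrom, n_genes and n_mutants must be >= 1")
        if self.read_len < len(self.upstream_anchor) + self.barcode_len:
            raise SimConfigError("read_len too short for anchor + barcode")
        # feasibility of non-overlapping gene packing, worst-case spans
        per_chrom = -(-self.n_genes // self.n_chrom)  # ceil
        need = 2 * _CHROM_MARGIN + per_chrom * _MAX_GENE_SPAN + (per_chrom + 1) * _MIN_GAP
        if need > self.chrom_len:
            raise SimConfigError(
                f"chrom_len={self.chrom_len} cannot hold {per_chrom} genes per "
                f"chromosome (worst case needs {need} bp): reduce n_genes or "
                f"increase chrom_len"
            )
        if 4 ** self.barcode_len < self.n_mutants:
            raise SimConfigError(
                f"barcode space 4^{self.barcode_len} smaller than n_mutants={self.n_mutants}"
            )

    def cassette_spec(self, max_anchor_mismatches: int = 1) -> CassetteSpec:
        return CassetteSpec(
            upstream_anchor=self.upstream_anchor,
            downstream_anchor=self.downstream_anchor,
            barcode_len=self.barcode_len,
            max_anchor_mismatches=max_anchor_mismatches,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SimConfigError(f"unknown simulate config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "fitness_ranges" in kwargs:
            kwargs["fitness_ranges"] = {
                cls_name: (tuple(ranges[0]), tuple(ranges[1]))
                for cls_name, ranges in kwargs["fitness_ranges"].items()
            }
        return cls(**kwargs)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent deterministic stream per stage
    return np.random.default_rng([stage, config.seed])


# ---------------------------------------------------------------------------
# reference genome and gene models


def generate_reference(config: SimConfig) -> tuple[dict[str, str], _annot.GeneModelSet]:
    """Random chromosomes plus non-overlapping multi-exon gene models.

    Each gene has a 5'UTR, at least two exons with introns, and a 3'UTR;
    strands are random.  Deterministic given the config seed.
    """
    rng = _rng(config, 0)
    genome: dict[str, str] = {}
    for c in range(config.n_chrom):
        codes = rng.integers(0, 4, size=config.chrom_len)
        genome[f"chr{c + 1}"] = _BASES[codes].tobytes().decode("ascii")

    # round-robin gene assignment to chromosomes
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1

    genes: list[_annot.GeneModel] = []
    gene_no = 0
    for c, n_on_chrom in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        if n_on_chrom == 0:
            continue
        structures = []
        for _ in range(n_on_chrom):
            n_ex = int(rng.integers(_N_EXONS[0], _N_EXONS[1] + 1))
            ex_lens = rng.integers(_EXON_LEN[0], _EXON_LEN[1] + 1, size=n_ex)
            in_lens = rng.integers(_INTRON_LEN[0], _INTRON_LEN[1] + 1, size=n_ex - 1)
            utr5 = int(rng.integers(_UTR_LEN[0], _UTR_LEN[1] + 1))
            utr3 = int(rng.integers(_UTR_LEN[0], _UTR_LEN[1] + 1))
            structures.append((ex_lens, in_lens, utr5, utr3))
        spans = [int(ex.sum() + ins.sum()) for ex, ins, _, _ in structures]
        slack = config.chrom_len - 2 * _CHROM_MARGIN - sum(spans) - (n_on_chrom + 1) * _MIN_GAP
        if slack < 0:
            raise SimConfigError(
                f"cannot pack {n_on_chrom} genes into {chrom} "
                f"(chrom_len={config.chrom_len})"
            )
        extra = rng.multinomial(slack, np.full(n_on_chrom + 1, 1.0 / (n_on_chrom + 1)))
        cursor = _CHROM_MARGIN + 1
        for i, (ex_lens, in_lens, utr5, utr3) in enumerate(structures):
            cursor += _MIN_GAP + int(extra[i])
            start = cursor
            exons = []
            p = start
            for j, el in enumerate(ex_lens):
                exons.append((p, p + int(el) - 1))
                p += int(el)
                if j < len(in_lens):
                    p += int(in_lens[j])
            end = exons[-1][1]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                five = ((start, start + utr5 - 1),)
                three = ((end - utr3 + 1, end),)
            else:
                five = ((end - utr5 + 1, end),)
                three = ((start, start + utr3 - 1),)
            gene_no += 1
            gid = f"g{gene_no:04d}"
            genes.append(
                _annot.GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=tuple(exons),
                    five_utrs=five,
                    three_utrs=three,
                    mrna_id=f"{gid}.t1",
                )
            )
            cursor = end + 1
    return genome, _annot.GeneModelSet(genes)


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# mutant library


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        codes = rng.integers(0, 4, size=(n - len(out), length))
        for row in _BASES[codes]:
            bc = row.tobytes().decode("ascii")
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def generate_library(
    config: SimConfig, genome: Mapping[str, str], genes: _annot.GeneModelSet
) -> pd.DataFrame:
    """Place ``n_mutants`` insertions uniformly over the genome.

    Returns the truth table: one row per mutant with barcode, locus,
    fitness class and fitnesses, the annotation category of its position
    (computed by the insertion classifier — single source of truth), the
    affected gene, and the expected screen classification under the
    noiseless abundance model and the default screen rule.
    """
    rng = _rng(config, 1)
    n = config.n_mutants
    n_cs = int(round(config.frac_cold_sensitive * n))
    n_con = int(round(config.frac_constitutive * n))
    if n_cs + n_con > n:
        raise SimConfigError("rounded class counts exceed n_mutants")
    classes = np.array(
        ["cold_sensitive"] * n_cs + ["constitutive"] * n_con + ["neutral"] * (n - n_cs - n_con),
        dtype=object,
    )
    classes = classes[rng.permutation(n)]

    chroms = list(genome)
    lens = np.array([len(genome[c]) for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n, p=lens / lens.sum())
    pos = np.array(
        [int(rng.integers(1, len(genome[chroms[i]]) + 1)) for i in chrom_idx]
    )
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    barcodes = _random_barcodes(rng, n, config.barcode_len)

    f_ctrl = np.empty(n)
    f_cold = np.empty(n)
    for cls_name, ((c_lo, c_hi), (k_lo, k_hi)) in config.fitness_ranges.items():
        mask = classes == cls_name
        m = int(mask.sum())
        if m == 0:
            continue
        f_ctrl[mask] = c_lo if c_lo == c_hi else rng.uniform(c_lo, c_hi, size=m)
        f_cold[mask] = k_lo if k_lo == k_hi else rng.uniform(k_lo, k_hi, size=m)

    truth = pd.DataFrame(
        {
            "mutant_id": [f"m{i + 1:05d}" for i in range(n)],
            "barcode": barcodes,
            "chrom": [chroms[i] for i in chrom_idx],
            "pos": pos,
            "strand": strand,
            "fitness_class": classes,
            "f_ctrl": f_ctrl,
            "f_cold": f_cold,
        }
    )

    cats, affected = [], []
    for chrom, p in zip(truth["chrom"], truth["pos"]):
        call = _annot.classify_insertion(chrom, int(p), genes)
        cats.append(call.category)
        affected.append(call.gene_id if call.gene_id is not None else "")
    truth["true_category"] = cats
    truth["affected_gene"] = affected

    # flanks that would run off a chromosome end come out truncated
    flank_truncated = []
    for chrom, p, s in zip(truth["chrom"], truth["pos"], truth["strand"]):
        L = len(genome[chrom])
        if s == "+":
            flank_truncated.append(int(p) + config.flank_len - 1 > L)
        else:
            flank_truncated.append(int(p) - config.flank_len + 1 < 1)
    truth["flank_truncated"] = flank_truncated

    # expected screen outcome under exact (noiseless) abundances
    ab = evolve_abundances(truth, config)
    r_ctrl = ab[_screen.CK2] / ab[_screen.CK1]
    r_cold = ab[_screen.S10] / ab[_screen.CK1]
    scfg = _screen.ScreenConfig()
    _, hit, direction, group = _screen.classify_rr(r_ctrl, r_cold, scfg)
    truth["expected_hit"] = hit
    truth["expected_direction"] = direction
    truth["expected_group"] = group
    return truth


def evolve_abundances(truth: pd.DataFrame, config: SimConfig) -> dict[str, np.ndarray]:
    """Exact relative abundances of every mutant in each sample.

    CK1 is uniform.  Growth multiplies a mutant's abundance by
    ``2**(f*g)``: CK2 applies (f_ctrl, g_ctrl) to CK1, S10 applies
    (f_cold, g_cold) to CK1, and S10R applies (f_ctrl, g_rec) to S10.
    Each vector is renormalised to sum to 1.
    """
    f_ctrl = truth["f_ctrl"].to_numpy(dtype=float)
    f_cold = truth["f_cold"].to_numpy(dtype=float)
    if (f_ctrl < 0).any() or (f_cold < 0).any():
        raise SimConfigError("fitness values must be non-negative")
    for name, g in (("g_ctrl", config.g_ctrl), ("g_cold", config.g_cold), ("g_rec", config.g_rec)):
        if g < 0:
            raise SimConfigError(f"{name} must be non-negative")
    n = len(truth)
    ck1 = np.full(n, 1.0 / n)

    def grow(base: np.ndarray, f: np.ndarray, g: float) -> np.ndarray:
        w = base * np.exp2(f * g)
        return w / w.sum()

    ck2 = grow(ck1, f_ctrl, config.g_ctrl)
    s10 = grow(ck1, f_cold, config.g_cold)
    s10r = grow(s10, f_ctrl, config.g_rec)
    return {_screen.CK1: ck1, _screen.CK2: ck2, _screen.S10: s10, _screen.S10R: s10r}


# ---------------------------------------------------------------------------
# read emission


def _seq_to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    lut[np.frombuffer(b"ACGT", dtype=np.uint8)] = np.arange(4)
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _codes_to_lines(codes: np.ndarray, lengths: np.ndarray | None) -> list[str]:
    """Rows of a (possibly padded) code matrix back to sequence strings."""
    ascii_rows = _BASES[np.clip(codes, 0, 3)]
    if lengths is None:
        return [row.tobytes().decode("ascii") for row in ascii_rows]
    return [
        row[:ln].tobytes().decode("ascii") for row, ln in zip(ascii_rows, lengths)
    ]


def _apply_substitutions(
    codes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-base substitutions at ``rate``; pad cells (code < 0) untouched."""
    if rate <= 0:
        return codes
    mask = (rng.random(codes.shape) < rate) & (codes >= 0)
    k = int(mask.sum())
    if k:
        codes = codes.copy()
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=k)) % 4
    return codes


def _write_fastq(path: Path, names: list[str], seqs: list[str]) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(names, seqs):
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


@dataclass
class EmitResult:
    """Paths of the emitted FASTQs plus the simulator's internal
    multinomial draws (per-mutant read counts per sample)."""

    barcode_fastqs: dict[str, Path]
    leap_fastqs: dict[str, tuple[Path, Path]]
    sampled_counts: pd.DataFrame      # mutants x samples, barcode-PCR draws
    leap_sampled_counts: pd.DataFrame  # mutants x LEAP samples


def emit_reads(
    truth: pd.DataFrame,
    abundances: Mapping[str, np.ndarray],
    config: SimConfig,
    outdir: str | Path,
    genome: Mapping[str, str] | None = None,
) -> EmitResult:
    """Sample reads for every sample and write FASTQ files.

    Barcode-PCR reads (all four samples) are ``upstream_anchor + barcode
    + downstream_anchor + backbone filler`` truncated to ``read_len``.
    LEAP-Seq pairs (CK1 and S10R) couple that cassette read with the
    genomic flank: ``flank_len`` bases read from the insertion position
    along the insertion strand (reverse-complemented for −), truncated at
    chromosome ends.  Substitution noise is applied per base; everything
    is deterministic given the config seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 2)
    n = len(truth)

    template = config.upstream_anchor + "{bc}" + config.downstream_anchor + _BACKBONE
    cassette_seqs = [
        template.format(bc=bc)[: config.read_len] for bc in truth["barcode"]
    ]
    cassette_codes = np.stack([_seq_to_codes(s) for s in cassette_seqs])

    barcode_fastqs: dict[str, Path] = {}
    counts = {}
    for sample in SAMPLES:
        draw = rng.multinomial(config.depth_per_sample, abundances[sample])
        counts[sample] = draw
        order = rng.permutation(np.repeat(np.arange(n), draw))
        codes = _apply_substitutions(cassette_codes[order], config.subst_error_rate, rng)
        names = [f"{sample}.bc.{i + 1}" for i in range(len(order))]
        path = outdir / f"{sample}.barcode.fastq"
        _write_fastq(path, names, _codes_to_lines(codes, None))
        barcode_fastqs[sample] = path

    leap_fastqs: dict[str, tuple[Path, Path]] = {}
    leap_counts = {}
    if genome is not None:
        flank_codes = np.full((n, config.flank_len), -1, dtype=np.int8)
        flank_lens = np.empty(n, dtype=int)
        for i, (chrom, p, s) in enumerate(
            zip(truth["chrom"], truth["pos"], truth["strand"])
        ):
            seq = genome[chrom]
            p = int(p)
            if s == "+":
                flank = seq[p - 1 : p - 1 + config.flank_len]
            else:
                flank = revcomp(seq[max(0, p - config.flank_len) : p])
            flank_lens[i] = len(flank)
            flank_codes[i, : len(flank)] = _seq_to_codes(flank)

        for sample in LEAP_SAMPLES:
            draw = rng.multinomial(config.depth_per_sample, abundances[sample])
            leap_counts[sample] = draw
            order = rng.permutation(np.repeat(np.arange(n), draw))
            c1 = _apply_substitutions(cassette_codes[order], config.subst_error_rate, rng)
            c2 = _apply_substitutions(flank_codes[order], config.subst_error_rate, rng)
            names = [f"{sample}.leap.{i + 1}" for i in range(len(order))]
            p1 = outdir / f"{sample}.leap_R1.fastq"
            p2 = outdir / f"{sample}.leap_R2.fastq"
            _write_fastq(p1, names, _codes_to_lines(c1, None))
            _write_fastq(p2, names, _codes_to_lines(c2, flank_lens[order]))
            leap_fastqs[sample] = (p1, p2)

    idx = truth["mutant_id"]
    return EmitResult(
        barcode_fastqs=barcode_fastqs,
        leap_fastqs=leap_fastqs,
        sampled_counts=pd.DataFrame(counts, index=idx),
        leap_sampled_counts=pd.DataFrame(leap_counts, index=idx),
    )


# ---------------------------------------------------------------------------
# one-call convenience


@dataclass
class SimOutput:
    genome: dict[str, str]
    genes: _annot.GeneModelSet
    truth: pd.DataFrame
    abundances: dict[str, np.ndarray]
    emitted: EmitResult
    fasta: Path
    gff3: Path
    truth_tsv: Path
    config_yaml: Path


def simulate_screen(config: SimConfig, outdir: str | Path) -> SimOutput:
    """Run the full generator and write genome, gene models, truth table,
    config snapshot and all FASTQ files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = generate_reference(config)
    truth = generate_library(config, genome, genes)
    abundances = evolve_abundances(truth, config)
    emitted = emit_reads(truth, abundances, config, outdir, genome=genome)

    fasta = outdir / "genome.fasta"
    gff3 = outdir / "genes.gff3"
    truth_tsv = outdir / "truth.tsv"
    config_yaml = outdir / "sim_config.yaml"
    write_fasta(genome, fasta)
    _annot.write_gff3(genes, gff3)
    truth.to_csv(truth_tsv, sep="\t", index=False)
    config.to_yaml(config_yaml)
    return SimOutput(
        genome=genome,
        genes=genes,
        truth=truth,
        abundances=abundances,
        emitted=emitted,
        fasta=fasta,
        gff3=gff3,
        truth_tsv=truth_tsv,
        config_yaml=config_yaml,
    )
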
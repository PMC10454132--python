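"""Synthetic drought time-course expression and genomic fixtures.

The expression simulator emulates a 9-condition x 3-replicate shoot
drought series (watered day 2/4; drought day 2, 3, 4, 7, 10, 14;
re-watered day 1).  Genes follow one of ~10 latent temporal archetypes,
including a transiently-up / transiently-down anticorrelated pair peaking
at drought day 4, and one planted low-noise hub gene whose profile is the
negative of the regulator archetype.  Signals live on the log2 scale
(x = baseline + amplitude * archetype(t) + Gaussian noise); stored
intensities are 2^x - 1 so that log2(x+1) recovers the signal, i.e. noise
is multiplicative on the intensity scale as is typical for microarrays.

The sequence simulator builds a contig from a motif-free low-complexity
background (CA-repeat), a gene model with exons/introns, and planted
concrete motif words; generation verifies that scanning recovers exactly
the planted instances and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from knoxnet.expression_io import ExpressionMatrix, ModuleAnnotation, SampleDesign
from knoxnet.motifs import (
    GenomicRegion,
    IUPACMotif,
    default_motifs,
    extract_introns,
    extract_promoter,
    scan_region,
)

#: the drought time-course design: (condition, day), in analysis order
DEFAULT_TIMEPOINTS: tuple[tuple[str, float], ...] = (
    ("watered", 2), ("watered", 4),
    ("drought", 2), ("drought", 3), ("drought", 4),
    ("drought", 7), ("drought", 10), ("drought", 14),
    ("rewatered", 1),
)

# unit-amplitude temporal shapes over the 9 default timepoints
# (W_2d, W_4d, D_2d, D_3d, D_4d, D_7d, D_10d, D_14d, reW_1d);
# five base shapes, each with its mirrored (down-regulated) twin, chosen
# mutually distinct (pairwise |r| < 0.5 after centering) so cluster
# recovery degrades gracefully with within-cluster heterogeneity
_BASE_SHAPES: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("transient", (0.0, 0.0, 0.0, 0.05, 1.0, 0.0, 0.05, 0.0, 0.3)),
    ("early", (0.0, 0.0, 1.0, 0.2, 0.0, 0.0, 0.0, 0.05, 0.3)),
    ("late", (0.0, 0.0, 0.05, 0.0, 0.0, 0.0, 1.0, 0.55, 0.3)),
    ("rewater", (0.0, 0.0, 0.2, 0.1, 0.15, 0.3, 0.15, 0.2, 1.0)),
    ("sustained", (0.05, 0.05, 0.9, 1.0, 0.95, 1.0, 0.95, 0.75, 0.15)),
)
DEFAULT_ARCHETYPES: tuple[tuple[str, tuple[float, ...]], ...] = tuple(
    item
    for name, shape in _BASE_SHAPES
    for item in (
        (f"{name}_up", shape),
        (f"{name}_down", tuple(-v for v in shape)),
    )
)

_MODULE_CYCLE = ("TF", "CK", "GA", "ABA", "oxidative_stress", "proline_metabolism")


@dataclass
class SimulationConfig:
    """Parameters of the expression simulator (defaults = study conditions)."""

    n_genes: int = 500
    archetypes: tuple[tuple[str, tuple[float, ...]], ...] = DEFAULT_ARCHETYPES
    timepoints: tuple[tuple[str, float], ...] = DEFAULT_TIMEPOINTS
    replicates: int = 3
    amplitude_range: tuple[float, float] = (1.0, 3.0)
    noise_sd: float = 0.25
    shape_sd: float = 0.4
    baseline: float = 6.0
    hub_regulators: int = 26
    hub_anticorrelated: bool = True
    hub_noise_factor: float = 0.2
    hub_probes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < len(self.archetypes):
            raise ValueError("need at least one gene per archetype")
        if self.replicates < 1 or self.noise_sd < 0:
            raise ValueError("invalid replicate count or noise sd")
        if self.baseline < 4 * self.noise_sd:
            raise ValueError("baseline must be >= 4 * noise_sd")
        for name, prof in self.archetypes:
            if len(prof) != len(self.timepoints):
                raise ValueError(
                    f"archetype {name!r} length != number of timepoints"
                )
        if not 0 < self.hub_regulators < self.n_genes:
            raise ValueError("hub_regulators out of range")
        if self.hub_probes < 1:
            raise ValueError("hub_probes must be >= 1")


@dataclass
class SyntheticExpressionTruth:
    """Planted structure: archetype labels, hub identity, amplitudes.

    The hub is a gene represented by several probe rows (as array designs
    routinely do for one transcript); ``hub_probe_ids`` lists them and
    ``hub`` names the gene.
    """

    archetype_of: dict[str, str]
    hub: str
    hub_probe_ids: list[str]
    regulators: list[str]
    amplitude_of: dict[str, float]
    clipped_values: int = 0

    def labels_for(self, probe_ids) -> list[str]:
        return [self.archetype_of[p] for p in probe_ids]


def _complement_basis(profiles: dict[str, np.ndarray], t: int) -> np.ndarray:
    """Projector onto the subspace orthogonal to all archetypes and to the
    constant vector (the directions row-scaling and clustering ignore)."""
    m = np.vstack([np.ones(t)] + [np.asarray(p, float) for p in profiles.values()])
    _, s, vt = np.linalg.svd(m, full_matrices=True)
    rank = int((s > 1e-10).sum())
    null = vt[rank:]
    return null.T @ null


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticExpressionTruth]:
    """Draw a planted expression matrix; deterministic given config.seed.

    Genes are split as evenly as possible across archetypes.  The hub is
    the first ``transient_down`` gene, regenerated with maximum amplitude
    and reduced noise so its profile is the cleanest in its cluster (the
    regulator archetype is ``transient_up``; its first ``hub_regulators``
    genes are the planted regulators).
    """
    rng = np.random.default_rng(config.seed)
    names = [n for n, _ in config.archetypes]
    profiles = {n: np.asarray(p, dtype=float) for n, p in config.archetypes}
    n_arch = len(names)
    counts = [config.n_genes // n_arch] * n_arch
    for i in range(config.n_genes - sum(counts)):
        counts[i] += 1

    gene_ids, labels = [], []
    for name, cnt in zip(names, counts):
        for i in range(cnt):
            gene_ids.append(f"G{len(gene_ids) + 1:04d}_{name}")
            labels.append(name)

    t = len(config.timepoints)
    samples = [
        SampleDesign(
            sample_id=f"{cond[0].upper() if cond != 'rewatered' else 'reW'}_"
            f"{day:g}d_r{rep}",
            condition=cond,
            day=day,
            replicate=rep,
        )
        for cond, day in config.timepoints
        for rep in range(1, config.replicates + 1)
    ]

    lo, hi = config.amplitude_range
    amplitudes = rng.uniform(lo, hi, size=config.n_genes)
    noise = rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, t * config.replicates)
    )
    # Per-gene deviation from the archetype shape, fixed across replicates:
    # emulates within-cluster heterogeneity (genes share a program but are
    # not copies), so the score filter and the |r| edge filter are real.
    # The jitter is drawn in the orthogonal complement of the archetype
    # span so heterogeneity decorrelates genes without displacing them
    # toward another cluster's centroid.
    shape_jitter = rng.normal(
        0.0, config.shape_sd, size=(config.n_genes, t)
    ) @ _complement_basis(profiles, t)

    hub_label = "transient_down" if config.hub_anticorrelated else "transient_up"
    reg_label = "transient_up"
    hub_candidates = [
        i for i, l in enumerate(labels) if l == hub_label
    ][: config.hub_probes]
    if len(hub_candidates) < config.hub_probes:
        raise ValueError("not enough genes in the hub archetype")
    regulators = [g for g, l in zip(gene_ids, labels) if l == reg_label][
        : config.hub_regulators
    ]
    # the hub gene is measured by several probe rows (arrays routinely
    # carry multiple probe sets per transcript); all track the archetype
    # exactly, at top amplitude and reduced measurement noise
    hub = gene_ids[hub_candidates[0]].split("_", 1)[0] + "_hub"
    hub_probe_ids = [f"{hub}.p{i + 1}" for i in range(config.hub_probes)]
    for pnum, idx in enumerate(hub_candidates):
        gene_ids[idx] = hub_probe_ids[pnum]
        amplitudes[idx] = hi
        noise[idx] *= config.hub_noise_factor
        shape_jitter[idx] = 0.0

    log_signal = np.empty((config.n_genes, t * config.replicates))
    for i, (lab, amp) in enumerate(zip(labels, amplitudes)):
        per_tp = config.baseline + amp * (profiles[lab] + shape_jitter[i])
        log_signal[i] = np.repeat(per_tp, config.replicates) + noise[i]

    intensities = np.exp2(log_signal) - 1.0
    clipped = int((intensities < 0).sum())
    intensities = np.clip(intensities, 0.0, None)

    matrix = ExpressionMatrix(
        probe_ids=gene_ids, samples=samples, values=intensities
    )
    truth = SyntheticExpressionTruth(
        archetype_of=dict(zip(gene_ids, labels)),
        hub=hub,
        hub_probe_ids=hub_probe_ids,
        regulators=regulators,
        amplitude_of=dict(zip(gene_ids, amplitudes)),
        clipped_values=clipped,
    )
    return matrix, truth


def annotation_for(
    truth: SyntheticExpressionTruth, seed_tag: str = "TALE"
) -> list[ModuleAnnotation]:
    """Module annotation for a simulated matrix.

    Each archetype maps to one functional module tag; the hub and its
    regulators additionally carry ``seed_tag`` so the network seed-set
    selection is exercised end to end.
    """
    arch_names = sorted(set(truth.archetype_of.values()))
    module_of = {
        a: _MODULE_CYCLE[i % len(_MODULE_CYCLE)]
        for i, a in enumerate(arch_names)
    }
    tale = {*truth.hub_probe_ids, *truth.regulators}
    annots = []
    for probe, arch in truth.archetype_of.items():
        gene = truth.hub if probe in truth.hub_probe_ids else probe.split("_")[0]
        tags = {module_of[arch]}
        if probe in tale:
            tags.add(seed_tag)
        annots.append(
            ModuleAnnotation(probe_id=probe, gene_id=gene, modules=tags)
        )
    return annots


# ---------------------------------------------------------------------------
# sequence simulation


@dataclass(frozen=True)
class PlantSpec:
    """One motif instance to plant: region kind/ordinal, strand, offset.

    ``offset`` is within the region's oriented sequence; None lets the
    generator pick a free position.
    """

    motif: str
    kind: str  # promoter | intron
    ordinal: int = 0
    strand: str = "+"
    offset: int | None = None


@dataclass
class SequenceSimConfig:
    contig_id: str = "chr_sim"
    gene_id: str = "gene_sim"
    strand: str = "+"
    promoter_length: int = 3000
    exon_lengths: tuple[int, ...] = (300, 200, 250, 180)
    intron_lengths: tuple[int, ...] = (400, 350, 187)
    downstream_pad: int = 60
    planted: tuple[PlantSpec, ...] = ()
    motifs: list[IUPACMotif] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly len(exons)-1 introns")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass
class SyntheticSequenceTruth:
    """Planted motif instances with their region-local and forward coords."""

    contig_id: str
    gene_id: str
    strand: str
    instances: list[dict] = field(default_factory=list)

    def count_by_kind(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for inst in self.instances:
            out[inst["kind"]] = out.get(inst["kind"], 0) + 1
        return out


_BACKGROUND_UNIT = "CA"


def _background(length: int) -> str:
    return (_BACKGROUND_UNIT * (length // 2 + 1))[:length]


def simulate_sequences(
    config: SequenceSimConfig,
) -> tuple[dict[str, str], str, SyntheticSequenceTruth]:
    """Build (genome dict, GFF3 text, truth) with planted motif words.

    Regions are CA-repeat background with concrete motif words (drawn from
    each motif's expansion; reverse-complemented for minus-strand plants)
    inserted at non-overlapping offsets.  After assembly the declared
    regions are scanned on both strands and the hit list must equal the
    planted truth exactly, otherwise generation fails.
    """
    rng = np.random.default_rng(config.seed)
    motifs = config.motifs if config.motifs is not None else default_motifs()
    motif_of = {m.name: m for m in motifs}
    guard = max(len(m) for m in motifs) if motifs else 8

    region_lengths: dict[tuple[str, int], int] = {
        ("promoter", 0): config.promoter_length
    }
    for i, ln in enumerate(config.intron_lengths, start=1):
        region_lengths[("intron", i)] = ln

    guard = 2 * guard  # spacing also shields junction re-validation windows
    region_seqs = {k: list(_background(v)) for k, v in region_lengths.items()}
    occupied: dict[tuple[str, int], list[tuple[int, int]]] = {
        k: [] for k in region_lengths
    }
    truth = SyntheticSequenceTruth(
        contig_id=config.contig_id,
        gene_id=config.gene_id,
        strand=config.strand,
    )

    for spec in config.planted:
        key = (spec.kind, spec.ordinal if spec.kind == "intron" else 0)
        if key not in region_lengths:
            raise ValueError(f"no such region {key} in gene model")
        motif = motif_of[spec.motif]
        length = region_lengths[key]
        if spec.offset is not None and _overlaps(
            spec.offset, len(motif), occupied[key], guard
        ):
            raise ValueError(
                f"planted instances overlap in region {key} at {spec.offset}"
            )
        # A concrete word abutting the background can create a spurious
        # match across the junction (e.g. the TGATGGGA tail GGA + CA...
        # contains GGACA, a KGACM word).  Each planted word is therefore
        # flanked by a TT spacer, inert against the motif set on both
        # strands, and the local window is re-scanned as a safety net.
        for _ in range(200):
            word = str(rng.choice(motif.expand()))
            planted_word = word if spec.strand == "+" else _revcomp(word)
            offset = (
                spec.offset
                if spec.offset is not None
                else _free_offset(rng, length, len(word), occupied[key], guard)
            )
            tentative = _place_with_spacer(
                region_seqs[key], planted_word, offset
            )
            if _junction_clean(tentative, planted_word, offset, spec, motifs):
                break
        else:
            raise ValueError(
                f"could not place {spec.motif} in region {key} without a "
                "spurious junction match"
            )
        occupied[key].append((offset - 2, offset + len(word) + 2))
        region_seqs[key] = tentative
        truth.instances.append(
            {
                "motif": spec.motif,
                "kind": spec.kind,
                "ordinal": key[1],
                "offset": offset,
                "strand": spec.strand,
                "matched": planted_word,
            }
        )

    genome, gff = _assemble(config, {k: "".join(v) for k, v in region_seqs.items()})
    _verify(genome, gff, config, motifs, truth)
    return genome, gff, truth


def _revcomp(word: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return word.translate(comp)[::-1]


def _overlaps(offset, length, taken, guard) -> bool:
    return any(
        offset < e + guard and s - guard < offset + length for s, e in taken
    )


def _place_with_spacer(region_chars, word, offset) -> list[str]:
    """Insert ``word`` at ``offset`` with TT spacers on both sides."""
    if offset < 0 or offset + len(word) > len(region_chars):
        raise ValueError(f"offset {offset} does not fit the region")
    out = list(region_chars)
    out[offset : offset + len(word)] = list(word)
    for k in (offset - 2, offset - 1, offset + len(word), offset + len(word) + 1):
        if 0 <= k < len(out):
            out[k] = "T"
    return out


def _junction_clean(tentative, word, offset, spec, motifs) -> bool:
    """The placed word must be the only hit in its local window."""
    pad = max(len(m) for m in motifs) + 2
    wstart = max(0, offset - pad)
    window = "".join(tentative[wstart : offset + len(word) + pad])
    reg = GenomicRegion("w", 0, len(window), "+", "promoter", 0, window)
    hits = [
        (h.motif, h.offset + wstart, h.strand_within_region)
        for h in scan_region(reg, motifs, strands="both")
    ]
    return hits == [(spec.motif, offset, spec.strand)]


def _free_offset(rng, region_len, word_len, taken, guard) -> int:
    for _ in range(200):
        offset = int(rng.integers(0, region_len - word_len + 1))
        if not _overlaps(offset, word_len, taken, guard):
            return offset
    raise ValueError("could not place motif instance without overlap")


def _assemble(
    config: SequenceSimConfig, region_seqs: dict[tuple[str, int], str]
) -> tuple[dict[str, str], str]:
    """Concatenate promoter/exons/introns into a contig and emit GFF3."""
    n_introns = len(config.intron_lengths)
    # transcript-order pieces (oriented sequences)
    pieces = []
    for i, ex_len in enumerate(config.exon_lengths):
        pieces.append(("exon", i + 1, _background(ex_len)))
        if i < n_introns:
            pieces.append(("intron", i + 1, region_seqs[("intron", i + 1)]))
    promoter = region_seqs[("promoter", 0)]

    gene_body = "".join(seq for _, _, seq in pieces)
    if config.strand == "+":
        contig = promoter + gene_body + _background(config.downstream_pad)
        gene_start = len(promoter)  # 0-based
        cursor = gene_start
        exon_coords = []
        for kind, _, seq in pieces:
            if kind == "exon":
                exon_coords.append((cursor, cursor + len(seq)))
            cursor += len(seq)
        gene_end = cursor
    else:
        # minus-strand gene: promoter lies beyond the gene end on the
        # forward strand and is stored reverse-complemented
        contig = (
            _background(config.downstream_pad)
            + _revcomp(gene_body)
            + _revcomp(promoter)
        )
        gene_start = config.downstream_pad
        gene_end = gene_start + len(gene_body)
        # exon forward coords, walking the gene body from its 3' (forward
        # left) end: transcript pieces reversed
        cursor = gene_start
        exon_coords = []
        for kind, _, seq in reversed(pieces):
            if kind == "exon":
                exon_coords.append((cursor, cursor + len(seq)))
            cursor += len(seq)
        exon_coords.sort()

    mrna_id = f"{config.gene_id}.1"
    lines = ["##gff-version 3"]
    lines.append(
        _gff_line(config.contig_id, "gene", gene_start, gene_end,
                  config.strand, f"ID={config.gene_id}")
    )
    lines.append(
        _gff_line(config.contig_id, "mRNA", gene_start, gene_end,
                  config.strand, f"ID={mrna_id};Parent={config.gene_id}")
    )
    for i, (s, e) in enumerate(exon_coords, start=1):
        lines.append(
            _gff_line(config.contig_id, "exon", s, e, config.strand,
                      f"ID={mrna_id}.exon{i};Parent={mrna_id}")
        )
    return {config.contig_id: contig}, "\n".join(lines) + "\n"


def _gff_line(seqid, ftype, start0, end0, strand, attrs) -> str:
    # 0-based half-open -> 1-based inclusive
    return f"{seqid}\tknoxnet_sim\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}"


def _verify(genome, gff, config, motifs, truth) -> None:
    import tempfile, os

    with tempfile.NamedTemporaryFile(
        "w", suffix=".gff3", delete=False
    ) as fh:
        fh.write(gff)
        gff_path = fh.name
    try:
        regions = [
            extract_promoter(genome, gff_path, config.gene_id,
                             config.promoter_length)
        ]
        regions.extend(extract_introns(genome, gff_path, config.gene_id))
        found = []
        for region in regions:
            for h in scan_region(region, motifs, strands="both"):
                found.append(
                    (h.motif, region.kind, region.ordinal, h.offset,
                     h.strand_within_region)
                )
        planted = [
            (i["motif"], i["kind"], i["ordinal"], i["offset"], i["strand"])
            for i in truth.instances
        ]
        if sorted(found) != sorted(planted):
            raise ValueError(
                "generated sequence scan does not match planted truth: "
                f"found {sorted(found)}, planted {sorted(planted)}"
            )
    finally:
        os.unlink(gff_path)


def write_sequences(
    genome: dict[str, str], gff: str, fasta_path, gff_path
) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write(gff)
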
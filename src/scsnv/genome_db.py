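"""Genome-wide scSNV enumeration and the tabular score database.

Every intron of a multi-exon transcript carries two splicing consensus
windows: donor -3..+8 around its 5' end and acceptor -12..+2 around its 3'
end.  Enumerating scSNVs means walking those windows, dropping the invariant
GT-AG positions (donor +1,+2; acceptor -2,-1), and emitting the three
possible substitutions of the reference base at each remaining position —
21 positions and 63 records per intron.  Minus-strand transcripts are
handled in transcript orientation and mapped back to plus-strand
coordinates, so ref/alt alleles are always plus-strand bases.

Records round-trip through a tab-delimited database dialect
(``#chr pos ref alt refseq_tx ensembl_tx site offset ada_score rf_score``,
"." for missing) and can be matched onto a VCF, adding ``SCSNV_ADA``,
``SCSNV_RF`` and ``SCSNV_SITE`` INFO fields.

Coordinates are 1-based inclusive everywhere at this module's surface
(matching VCF and the db dialect); any half-open arithmetic is internal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .regions import donor_region, acceptor_region

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
BASES = "ACGT"

DB_COLUMNS = (
    "chr",
    "pos",
    "ref",
    "alt",
    "refseq_tx",
    "ensembl_tx",
    "site",
    "offset",
    "ada_score",
    "rf_score",
)


@dataclass(frozen=True)
class ScsnvRecord:
    chrom: str
    pos: int  # 1-based, plus strand
    ref: str
    alt: str
    gene_id: str = ""
    transcript_ids: tuple = ()
    site_kind: str = ""  # donor | acceptor
    offset: int = 0
    region_side: str = ""  # exonic | intronic
    ada_score: float | None = None
    rf_score: float | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for s in (self.ada_score, self.rf_score):
            if s is not None and not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} outside [0, 1]")

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GeneModel:
    """One transcript: ordered exon intervals in transcription order.

    ``exons`` are 1-based inclusive (start, end) genomic intervals with
    start <= end, listed 5'->3' along the transcript: ascending genomic
    coordinates on '+', descending on '-'.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list
    gene_id: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript needs at least one exon")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon interval ({s}, {e}) reversed")
        starts = [s for s, _ in self.exons]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise ValueError("exons not in transcription order")
        flat = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(flat, flat[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")

    def introns(self) -> list:
        """Genomic intron intervals (1-based inclusive) in transcription order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out


def _genome_base(genome, chrom: str, pos: int) -> str:
    """Plus-strand reference base at a 1-based position."""
    if isinstance(genome, dict):
        if chrom not in genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = genome[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"{chrom}:{pos} outside sequence (length {len(seq)})")
        return seq[pos - 1].upper()
    # pyfaidx.Fasta or similar mapping of chrom -> indexable sequence
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    return str(genome[chrom][pos - 1 : pos]).upper()


def _chrom_length(genome, chrom: str) -> int:
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    return len(genome[chrom])


def _site_positions(model: GeneModel, intron) -> list:
    """(site_kind, offset, region_side, genomic_pos) for one intron's windows."""
    istart, iend = intron
    plus = model.strand == "+"
    # transcript-orientation ends of the intron on the genome
    five_prime = istart if plus else iend  # first intronic base at the donor
    three_prime = iend if plus else istart  # last intronic base at the acceptor
    step = 1 if plus else -1
    out = []
    donor = donor_region()
    for off in donor.mutable_offsets:
        if off > 0:  # intronic, walking into the intron
            pos = five_prime + step * (off - 1)
        else:  # exonic, walking back into the upstream exon
            pos = five_prime - step * (-off)
        out.append(("donor", off, "exonic" if off < 0 else "intronic", pos))
    acceptor = acceptor_region()
    for off in acceptor.mutable_offsets:
        if off < 0:  # intronic, walking back from the intron's 3' end
            pos = three_prime - step * (-off - 1)
        else:  # exonic, first bases of the downstream exon
            pos = three_prime + step * off
        out.append(("acceptor", off, "intronic" if off < 0 else "exonic", pos))
    return out


def enumerate_scsnvs(models, genome) -> list:
    """All potential scSNVs for the given transcripts.

    Per intron: 9 donor + 12 acceptor mutable positions x 3 alternative
    alleles = 63 records.  Records duplicated across transcripts are merged
    with a union of transcript ids (first-seen site identity kept).
    Returned sorted by (chrom, pos, ref, alt).
    """
    merged: dict = {}
    for model in models:
        chrom_len = _chrom_length(genome, model.chrom)
        for s, e in model.exons:
            if not (1 <= s and e <= chrom_len):
                raise ValueError(
                    f"exon ({s}, {e}) of {model.transcript_id} outside {model.chrom} "
                    f"(length {chrom_len})"
                )
        for intron in model.introns():
            for site_kind, offset, side, pos in _site_positions(model, intron):
                ref = _genome_base(genome, model.chrom, pos)
                for alt in BASES:
                    if alt == ref:
                        continue
                    key = (model.chrom, pos, ref, alt)
                    if key in merged:
                        old = merged[key]
                        if model.transcript_id not in old.transcript_ids:
                            merged[key] = replace(
                                old,
                                transcript_ids=old.transcript_ids
                                + (model.transcript_id,),
                            )
                    else:
                        merged[key] = ScsnvRecord(
                            chrom=model.chrom,
                            pos=pos,
                            ref=ref,
                            alt=alt,
                            gene_id=model.gene_id,
                            transcript_ids=(model.transcript_id,),
                            site_kind=site_kind,
                            offset=offset,
                            region_side=side,
                        )
    return sorted(merged.values(), key=lambda r: r.key)


def classify_variant(chrom, pos, ref, alt, models, genome=None) -> list:
    """Consensus-region hits for one variant: (site_kind, offset, region_side).

    Empty list means the variant is not an scSNV: outside every window, at a
    GT-AG position, or not a single-nucleotide substitution.  With a genome
    supplied, a reference mismatch is reported as a warning, not an error.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return []
    if genome is not None:
        actual = _genome_base(genome, chrom, pos)
        if actual != ref.upper():
            warnings.warn(
                f"{chrom}:{pos} reference is {actual}, variant claims {ref}"
            )
    hits = []
    for model in models:
        if model.chrom != chrom:
            continue
        for intron in model.introns():
            for site_kind, offset, side, p in _site_positions(model, intron):
                if p == pos:
                    entry = (site_kind, offset, side)
                    if entry not in hits:
                        hits.append(entry)
    return hits


# -- tab-delimited db dialect ------------------------------------------------


def _fmt_score(s) -> str:
    return "." if s is None else f"{s:.4f}"


def write_db(records, path) -> None:
    """Write records (sorted by chrom, pos) in the db dialect."""
    records = list(records)
    keys = [(r.chrom, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, pos) before writing")
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DB_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.pos),
                        r.ref,
                        r.alt,
                        ";".join(r.transcript_ids) or ".",
                        ".",
                        r.site_kind or ".",
                        str(r.offset),
                        _fmt_score(r.ada_score),
                        _fmt_score(r.rf_score),
                    ]
                )
                + "\n"
            )


def read_db(path) -> list:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(DB_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(DB_COLUMNS)} fields, got {len(parts)}"
                )
            try:
                site = "" if parts[6] == "." else parts[6]
                offset = int(parts[7])
                if site == "donor":
                    side = "exonic" if offset < 0 else "intronic"
                elif site == "acceptor":
                    side = "intronic" if offset < 0 else "exonic"
                else:
                    side = ""
                records.append(
                    ScsnvRecord(
                        chrom=parts[0],
                        pos=int(parts[1]),
                        ref=parts[2],
                        alt=parts[3],
                        transcript_ids=tuple(
                            t for t in parts[4].split(";") if t and t != "."
                        ),
                        site_kind=site,
                        offset=offset,
                        region_side=side,
                        ada_score=None if parts[8] == "." else float(parts[8]),
                        rf_score=None if parts[9] == "." else float(parts[9]),
                    )
                )
            except (ValueError, IndexError) as exc:
                if "expected" in str(exc):
                    raise
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
    return records


def query(records, chrom=None, pos=None, ref=None, alt=None, region=None) -> list:
    """Exact-variant or half-open region lookup over a record list.

    ``region`` is (chrom, start, end) with start inclusive, end exclusive.
    """
    if region is not None:
        rchrom, start, end = region
        return [r for r in records if r.chrom == rchrom and start <= r.pos < end]
    out = [r for r in records if r.chrom == chrom and r.pos == pos]
    if ref is not None:
        out = [r for r in out if r.ref == ref]
    if alt is not None:
        out = [r for r in out if r.alt == alt]
    return out


def attach_scores(records, ada_scores=None, rf_scores=None) -> list:
    """Return records with per-record scores filled in (None allowed)."""
    records = list(records)
    n = len(records)
    ada_scores = [None] * n if ada_scores is None else list(ada_scores)
    rf_scores = [None] * n if rf_scores is None else list(rf_scores)
    out = []
    for r, a, f in zip(records, ada_scores, rf_scores):
        a = None if a is None or (isinstance(a, float) and a != a) else float(a)
        f = None if f is None or (isinstance(f, float) and f != f) else float(f)
        out.append(replace(r, ada_score=a, rf_score=f))
    return out


# -- VCF annotation ----------------------------------------------------------

_INFO_HEADERS = [
    ('##INFO=<ID=SCSNV_ADA,Number=1,Type=Float,'
     'Description="AdaBoost splice-altering probability">'),
    ('##INFO=<ID=SCSNV_RF,Number=1,Type=Float,'
     'Description="Random forest splice-altering probability">'),
    ('##INFO=<ID=SCSNV_SITE,Number=1,Type=String,'
     'Description="Splice site and offset (e.g. donor+5)">'),
]


def annotate_vcf(vcf_in, records, vcf_out) -> int:
    """Tag matching VCF records with scSNV INFO fields; returns match count.

    Matching is exact on (chrom, pos, ref, alt).  Non-matching records pass
    through untouched and input ordering is preserved.
    """
    import pysam

    index = {r.key: r for r in records}
    n_matched = 0
    with pysam.VariantFile(str(vcf_in)) as vin:
        header = vin.header.copy()
        for line in _INFO_HEADERS:
            header.add_line(line)
        with pysam.VariantFile(str(vcf_out), "w", header=header) as vout:
            for rec in vin:
                rec.translate(header)  # rebind to the extended header in place
                for alt in rec.alts or ():
                    hit = index.get((rec.chrom, rec.pos, rec.ref, alt))
                    if hit is None:
                        continue
                    n_matched += 1
                    if hit.ada_score is not None:
                        rec.info["SCSNV_ADA"] = hit.ada_score
                    if hit.rf_score is not None:
                        rec.info["SCSNV_RF"] = hit.rf_score
                    sign = "+" if hit.offset > 0 else ""
                    rec.info["SCSNV_SITE"] = f"{hit.site_kind}{sign}{hit.offset}"
                vout.write(rec)
    return n_matched


# -- gene-model input --------------------------------------------------------


def read_gene_models_gtf(path) -> list:
    """Transcript models from GTF/GFF exon features (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    grouped: dict = {}
    for exon in db.features_of_type("exon"):
        tx = exon.attributes.get("transcript_id", ["?"])[0]
        gene = exon.attributes.get("gene_id", [""])[0]
        grouped.setdefault(tx, {"chrom": exon.seqid, "strand": exon.strand,
                                "gene": gene, "exons": []})
        grouped[tx]["exons"].append((exon.start, exon.end))
    models = []
    for tx, d in grouped.items():
        exons = sorted(d["exons"], reverse=d["strand"] == "-")
        models.append(GeneModel(tx, d["chrom"], d["strand"], exons, d["gene"]))
    return models


def read_gene_models_refflat(path) -> list:
    """Transcript models from refFlat (geneName name chrom strand txStart
    txEnd cdsStart cdsEnd exonCount exonStarts exonEnds; half-open starts)."""
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            gene, tx, chrom, strand = f[0], f[1], f[2], f[3]
            starts = [int(x) + 1 for x in f[9].rstrip(",").split(",")]
            ends = [int(x) for x in f[10].rstrip(",").split(",")]
            exons = list(zip(starts, ends))
            if strand == "-":
                exons = exons[::-1]
            models.append(GeneModel(tx, chrom, strand, exons, gene))
    return models


def read_gene_models(path, fmt: str = "gtf") -> list:
    if fmt in ("gtf", "gff", "gff3"):
        return read_gene_models_gtf(path)
    if fmt == "refflat":
        return read_gene_models_refflat(path)
    raise ValueError(f"unknown gene-model format {fmt!r}")


def open_genome(path):
    """FASTA accessor (pyfaidx) usable wherever a genome mapping is expected."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)
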
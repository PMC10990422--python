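"""Readers and writers for the package's plain-text interchange formats.

Panel: BED4 (0-based half-open) plus a side-car TSV of motif/flank/selection
columns.  Genotypes, candidates, ages, and reads are TSV; reads can also be
written to and read from SAM (via pysam), with the sample and locus carried
in ``sm``/``lo`` tags.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .panel import STRLocus
from .reads import ReadRecord
from .simulate import MISSING, QuadFamily


# -- panel -----------------------------------------------------------------

def write_panel(panel: list[STRLocus], bed_path, info_path) -> None:
    with open(bed_path, "w") as bed:
        for loc in panel:
            bed.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\n")
    rows = [{
        "locus_id": loc.locus_id, "motif": loc.motif, "period": loc.period,
        "ref_repeat_count": loc.ref_repeat_count, "flank_left": loc.flank_left,
        "flank_right": loc.flank_right,
        "s": "" if loc.s_coefficient is None else loc.s_coefficient,
        "hotspot": int(loc.hotspot),
    } for loc in panel]
    pd.DataFrame(rows).to_csv(info_path, sep="\t", index=False)


def read_panel(bed_path, info_path) -> list[STRLocus]:
    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["chrom", "start", "end", "locus_id"])
    info = pd.read_csv(info_path, sep="\t").set_index("locus_id")
    panel = []
    for _, row in bed.iterrows():
        meta = info.loc[row["locus_id"]]
        s = meta["s"]
        panel.append(STRLocus(
            locus_id=row["locus_id"], chrom=row["chrom"], start=int(row["start"]),
            period=int(meta["period"]), motif=meta["motif"],
            ref_repeat_count=int(meta["ref_repeat_count"]),
            flank_left=meta["flank_left"], flank_right=meta["flank_right"],
            s_coefficient=None if pd.isna(s) else float(s),
            hotspot=bool(meta["hotspot"]),
        ))
    return panel


# -- genotypes / candidates / ages ----------------------------------------

def write_genotypes(families: list[QuadFamily], panel: list[STRLocus], path) -> None:
    """Called parental genotypes and child genotypes, one row per sample-locus."""
    with open(path, "w") as fh:
        fh.write("sample\tlocus_id\tallele1_ru\tallele2_ru\n")
        for fam in families:
            members = [
                (fam.father_id, fam.father_called),
                (fam.mother_id, fam.mother_called),
                (fam.child_id(0), fam.child_true[0]),
                (fam.child_id(1), fam.child_true[1]),
            ]
            for sample, gts in members:
                for k, loc in enumerate(panel):
                    a, b = sorted(int(x) for x in gts[k])
                    a = "." if a == MISSING else a
                    b = "." if b == MISSING else b
                    fh.write(f"{sample}\t{loc.locus_id}\t{a}\t{b}\n")


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=".")
    for col in ("allele1_ru", "allele2_ru"):
        df[col] = df[col].fillna(MISSING).astype(int)
    return df


def write_candidates(candidates: pd.DataFrame, path) -> None:
    candidates.to_csv(path, sep="\t", index=False)


def read_candidates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ages(families: list[QuadFamily], path) -> None:
    rows = []
    for fam in families:
        for c in range(2):
            rows.append({"family": fam.family_id, "child": fam.child_id(c),
                         "role": fam.child_role(c),
                         "father_age": round(fam.father_age[c], 3),
                         "mother_age": round(fam.mother_age[c], 3)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ages(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- reads -----------------------------------------------------------------

READ_COLUMNS = ["read_id", "sample", "locus_id", "pos", "sequence", "mapq",
                "is_primary", "softclip_left", "softclip_right"]


def write_reads_tsv(reads: list[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(READ_COLUMNS) + "\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.sample}\t{r.locus_id}\t{r.pos}\t{r.seq}\t"
                     f"{r.mapq}\t{int(r.is_primary)}\t{r.softclip_left}\t"
                     f"{r.softclip_right}\n")


def read_reads_tsv(path) -> list[ReadRecord]:
    df = pd.read_csv(path, sep="\t")
    return [ReadRecord(read_id=row.read_id, sample=row.sample, locus_id=row.locus_id,
                       pos=int(row.pos), seq=row.sequence, mapq=int(row.mapq),
                       is_primary=bool(row.is_primary),
                       softclip_left=int(row.softclip_left),
                       softclip_right=int(row.softclip_right))
            for row in df.itertuples()]


def write_sam(reads: list[ReadRecord], panel: list[STRLocus], path) -> None:
    chroms: dict[str, int] = {}
    for loc in panel:
        chroms[loc.chrom] = max(chroms.get(loc.chrom, 0), loc.end + 10_000)
    chrom_of = {loc.locus_id: loc.chrom for loc in panel}
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": c, "LN": n} for c, n in chroms.items()]}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        tid = {c: k for k, c in enumerate(chroms)}
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r.read_id
            a.query_sequence = r.seq
            a.flag = 0 if r.is_primary else 0x100
            a.reference_id = tid[chrom_of[r.locus_id]]
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            cigar = []
            if r.softclip_left:
                cigar.append((4, r.softclip_left))
            cigar.append((0, len(r.seq) - r.softclip_left - r.softclip_right))
            if r.softclip_right:
                cigar.append((4, r.softclip_right))
            a.cigar = cigar
            a.set_tag("sm", r.sample)
            a.set_tag("lo", r.locus_id)
            sam.write(a)


def read_sam(path) -> list[ReadRecord]:
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam:
            scl = scr = 0
            if a.cigartuples:
                if a.cigartuples[0][0] == 4:
                    scl = a.cigartuples[0][1]
                if len(a.cigartuples) > 1 and a.cigartuples[-1][0] == 4:
                    scr = a.cigartuples[-1][1]
            out.append(ReadRecord(
                read_id=a.query_name,
                sample=a.get_tag("sm") if a.has_tag("sm") else "",
                locus_id=a.get_tag("lo") if a.has_tag("lo") else "",
                pos=int(a.reference_start),
                seq=a.query_sequence or "",
                mapq=int(a.mapping_quality),
                is_primary=not a.is_secondary,
                softclip_left=scl,
                softclip_right=scr,
            ))
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
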
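"""File formats: FASTA segments, BedGraph end tracks, TSV tables, metadata.

Conventions, stated once:

* Internal coordinates are 1-based residue-inclusive; BedGraph on disk is
  0-based half-open, so internal position ``p`` maps to the interval
  ``[p-1, p)``.  Strand is encoded in the filename suffix
  (``.top.bedgraph`` / ``.bottom.bedgraph``) and in the header.
* Tables are TSV: tab-separated, header row, no quoting, ``#`` metadata
  lines on top.  Every output carries a metadata header (tool version,
  seed, config hash) so reruns with an identical config are byte-identical.
* FASTA is read/written with Biopython; DNA input is accepted only behind
  the explicit ``dna_to_rna`` flag (T -> U transliteration).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .geometry import DsSegment
from .kinetics import TimeCourse
from .sites import CalledSite, EndCountTrack
from .specificity import VariantRateRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "track_filename",
    "read_sites_tsv",
    "write_sites_tsv",
    "read_timecourses_tsv",
    "write_timecourses_tsv",
    "read_variant_rates_tsv",
    "write_variant_rates_tsv",
    "config_hash",
    "metadata_lines",
    "write_run_metadata",
]


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def metadata_lines(**meta) -> list[str]:
    """'#key=value' header lines, always starting with the tool version."""
    lines = [f"# minicleave={__version__}"]
    lines += [f"# {k}={v}" for k, v in meta.items()]
    lines.append("# coordinates=1-based residue-inclusive; bond named by the residue 5' of it")
    return lines


def read_fasta(path, *, dna_to_rna: bool = False) -> list[DsSegment]:
    segments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if dna_to_rna:
            seq = seq.replace("T", "U")
        segments.append(DsSegment(id=rec.id, top_sequence=seq))
    if not segments:
        raise ValueError(f"no FASTA records in {path}")
    return segments


def write_fasta(segments: list[DsSegment], path) -> None:
    records = [
        SeqRecord(Seq(s.top_sequence), id=s.id, description="top strand 5'->3'")
        for s in segments
    ]
    SeqIO.write(records, str(path), "fasta")


def track_filename(segment_id: str, strand: str) -> str:
    return f"{segment_id}.{strand}.bedgraph"


def write_bedgraph(track: EndCountTrack, path, **meta) -> None:
    """One line per nonzero position: ``segment  p-1  p  count`` (0-based
    half-open)."""
    lines = metadata_lines(
        segment=track.segment_id, strand=track.strand, length=track.length, **meta
    )
    for pos in sorted(track.counts):
        c = track.counts[pos]
        if c:
            lines.append(f"{track.segment_id}\t{pos - 1}\t{pos}\t{c}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bedgraph(
    path, segment_id: str | None = None, strand: str | None = None, length: int | None = None
) -> EndCountTrack:
    """Read an end track; header metadata supplies strand/length unless
    overridden.  Intervals wider than one position spread their count over
    each covered position."""
    counts: dict[int, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if "=" in body:
                k, _, v = body.partition("=")
                if k == "strand" and strand is None:
                    strand = v
                elif k == "length" and length is None:
                    length = int(v)
                elif k == "segment" and segment_id is None:
                    segment_id = v
            continue
        if line.startswith("track"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
        seg, start, end, count = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
        if segment_id is None:
            segment_id = seg
        if start < 0 or end <= start:
            raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        if count < 0:
            raise ValueError(f"{path}:{lineno}: negative count")
        for p in range(start + 1, end + 1):  # 0-based half-open -> 1-based positions
            counts[p] = counts.get(p, 0) + count
    if strand is None:
        name = Path(path).name
        for cand in ("top", "bottom"):
            if f".{cand}." in name:
                strand = cand
        if strand is None:
            raise ValueError(f"{path}: strand not in header, filename or arguments")
    if length is None:
        if not counts:
            raise ValueError(f"{path}: empty track with no length header")
        length = max(counts)
    if segment_id is None:
        raise ValueError(f"{path}: segment id not found")
    return EndCountTrack(segment_id=segment_id, strand=strand, length=length, counts=counts)


def _write_tsv(df: pd.DataFrame, path, **meta) -> None:
    header = "\n".join(metadata_lines(**meta))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_sites_tsv(sites: list[CalledSite], path, **meta) -> None:
    df = pd.DataFrame(
        {
            "segment": [s.segment_id for s in sites],
            "i_top": [s.i_top for s in sites],
            "top_support": [s.top_support for s in sites],
            "bottom_support": [s.bottom_support for s in sites],
            "weight": [s.weight for s in sites],
        }
    )
    _write_tsv(df, path, **meta)


def read_sites_tsv(path) -> list[CalledSite]:
    df = _read_tsv(path)
    return [
        CalledSite(
            segment_id=str(r.segment),
            i_top=int(r.i_top),
            top_support=int(r.top_support),
            bottom_support=int(r.bottom_support),
        )
        for r in df.itertuples()
    ]


def write_timecourses_tsv(courses: list[TimeCourse], path, **meta) -> None:
    rows = []
    for tc in courses:
        for t, f in zip(tc.times, tc.fractions):
            rows.append(
                {
                    "substrate_id": tc.substrate_id,
                    "enzyme_id": tc.enzyme_id,
                    "enzyme_amount": tc.enzyme_amount,
                    "time_min": t,
                    "fraction": f,
                }
            )
    _write_tsv(pd.DataFrame(rows), path, **meta)


def read_timecourses_tsv(path) -> list[TimeCourse]:
    df = _read_tsv(path)
    out = []
    for (sub, enz, amt), grp in df.groupby(
        ["substrate_id", "enzyme_id", "enzyme_amount"], sort=True
    ):
        grp = grp.sort_values("time_min")
        out.append(
            TimeCourse(
                substrate_id=str(sub),
                enzyme_id=str(enz),
                enzyme_amount=float(amt),
                times=[float(t) for t in grp["time_min"]],
                fractions=[float(f) for f in grp["fraction"]],
            )
        )
    return out


def write_variant_rates_tsv(records: list[VariantRateRecord], path, **meta) -> None:
    df = pd.DataFrame(
        {
            "position": [r.position for r in records],
            "base": [r.base for r in records],
            "relative_rate": [r.relative_rate for r in records],
            "label": [r.label if r.label is not None else "" for r in records],
        }
    )
    _write_tsv(df, path, **meta)


def read_variant_rates_tsv(path) -> list[VariantRateRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"label": str})
    out = []
    for r in df.itertuples():
        label = getattr(r, "label", None)
        if label is not None and (pd.isna(label) or label == ""):
            label = None
        out.append(
            VariantRateRecord(
                position=int(r.position),
                base=str(r.base),
                relative_rate=float(r.relative_rate),
                label=str(label) if label is not None else None,
            )
        )
    return out


def write_run_metadata(path, config: dict, seed: int | None = None) -> None:
    payload = {
        "tool": "minicleave",
        "version": __version__,
        "seed": seed if seed is not None else config.get("seed"),
        "config_hash": config_hash(config),
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
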
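"""File formats: panel TSV, frequency CSV, count TSV, profile JSON.

The count interchange format is a strict-header TSV (sample_id, locus_id,
allele, reads_fwd, reads_rev) — per-strand per-allele counts have no
canonical VCF encoding, and a flat TSV stays diff-able. Profiles round-trip
through canonicalised JSON (sorted keys, fixed indentation) so reruns are
byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .core import (
    CALLED,
    NO_CALL,
    AlleleCounts,
    FrequencyTable,
    GenotypeCall,
    LocusDef,
    Profile,
    panel_index,
)

COUNTS_COLUMNS = ["sample_id", "locus_id", "allele", "reads_fwd", "reads_rev"]
PANEL_COLUMNS = ["locus_id", "chrom_class", "allele1", "allele2", "amplicon_length"]
FREQ_COLUMNS = ["locus_id", "allele", "frequency", "population"]


def write_panel_tsv(panel: Sequence[LocusDef], path: str | Path) -> None:
    rows = [
        {
            "locus_id": l.locus_id,
            "chrom_class": l.chrom_class,
            "allele1": l.alleles[0],
            "allele2": l.alleles[1],
            "amplicon_length": l.amplicon_length,
        }
        for l in panel
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path) -> list[LocusDef]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != PANEL_COLUMNS:
        raise ValueError(f"panel TSV must have columns {PANEL_COLUMNS}")
    return [
        LocusDef(
            locus_id=row.locus_id,
            chrom_class=row.chrom_class,
            alleles=(row.allele1, row.allele2),
            amplicon_length=int(row.amplicon_length),
        )
        for row in df.itertuples()
    ]


def write_frequency_csv(freqs: FrequencyTable, path: str | Path) -> None:
    rows = []
    for locus_id in sorted(freqs.freqs):
        for allele in sorted(freqs.freqs[locus_id]):
            rows.append(
                {
                    "locus_id": locus_id,
                    "allele": allele,
                    "frequency": repr(freqs.freqs[locus_id][allele]),
                    "population": freqs.population,
                }
            )
    pd.DataFrame(rows, columns=FREQ_COLUMNS).to_csv(path, index=False)


def read_frequency_csv(path: str | Path) -> FrequencyTable:
    df = pd.read_csv(path, dtype={"locus_id": str, "allele": str, "population": str})
    if list(df.columns) != FREQ_COLUMNS:
        raise ValueError(f"frequency CSV must have columns {FREQ_COLUMNS}")
    populations = set(df["population"])
    if len(populations) != 1:
        raise ValueError(f"frequency CSV mixes populations: {sorted(populations)}")
    freqs: dict[str, dict[str, float]] = {}
    for row in df.itertuples():
        freqs.setdefault(row.locus_id, {})[row.allele] = float(row.frequency)
    return FrequencyTable(population=populations.pop(), freqs=freqs)


def write_counts_tsv(samples: Sequence[AlleleCounts], path: str | Path) -> None:
    rows = []
    for s in samples:
        for locus_id in sorted(s.counts):
            for allele in sorted(s.counts[locus_id]):
                fwd, rev = s.counts[locus_id][allele]
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "locus_id": locus_id,
                        "allele": allele,
                        "reads_fwd": fwd,
                        "reads_rev": rev,
                    }
                )
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts_tsv(
    path: str | Path, panel: Optional[Sequence[LocusDef]] = None
) -> dict[str, AlleleCounts]:
    """Parse a counts TSV into per-sample AlleleCounts.

    Malformed rows are reported with their (1-based, header-inclusive) line
    number; duplicate (sample, locus, allele) rows and, when a panel is
    given, unknown loci/alleles are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != COUNTS_COLUMNS:
        raise ValueError(f"counts TSV must have columns {COUNTS_COLUMNS}")
    idx = panel_index(panel) if panel is not None else None
    out: dict[str, AlleleCounts] = {}
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(df.itertuples(), start=2):
        line = f"{path} line {i}"
        if any(
            pd.isna(v)
            for v in (row.sample_id, row.locus_id, row.allele, row.reads_fwd, row.reads_rev)
        ):
            raise ValueError(f"{line}: missing field")
        try:
            fwd, rev = int(row.reads_fwd), int(row.reads_rev)
        except ValueError:
            raise ValueError(f"{line}: non-integer read count") from None
        if fwd < 0 or rev < 0:
            raise ValueError(f"{line}: negative read count")
        key = (row.sample_id, row.locus_id, row.allele)
        if key in seen:
            raise ValueError(f"{line}: duplicate row for {key}")
        seen.add(key)
        if idx is not None:
            locus = idx.get(row.locus_id)
            if locus is None:
                raise ValueError(f"{line}: unknown locus {row.locus_id}")
            if row.allele not in locus.alleles:
                raise ValueError(f"{line}: allele {row.allele} not at {row.locus_id}")
        sample = out.setdefault(row.sample_id, AlleleCounts(row.sample_id, {}))
        sample.counts.setdefault(row.locus_id, {})[row.allele] = (fwd, rev)
    return out


def profile_to_dict(profile: Profile) -> dict:
    calls = {}
    for locus_id in sorted(profile.calls):
        c = profile.calls[locus_id]
        calls[locus_id] = {
            "status": c.status,
            "genotype": list(c.genotype),
            "coverage": c.coverage,
            "minor_fraction": c.minor_fraction,
            "flags": sorted(c.flags),
            "no_call_reason": c.no_call_reason,
            "y_dropin_allele": c.y_dropin_allele,
        }
    return {
        "sample_id": profile.sample_id,
        "sex_markers_present": profile.sex_markers_present,
        "calls": calls,
    }


def profile_from_dict(data: dict) -> Profile:
    required = {"sample_id", "sex_markers_present", "calls"}
    missing = required - set(data)
    if missing:
        raise ValueError(f"profile JSON missing fields: {sorted(missing)}")
    calls = {}
    for locus_id, c in data["calls"].items():
        extra = set(c) - {
            "status", "genotype", "coverage", "minor_fraction",
            "flags", "no_call_reason", "y_dropin_allele",
        }
        if extra:
            raise ValueError(f"{locus_id}: unknown profile fields {sorted(extra)}")
        # GenotypeCall enforces the call invariants (flag/genotype consistency)
        calls[locus_id] = GenotypeCall(
            locus_id=locus_id,
            status=c["status"],
            genotype=tuple(c["genotype"]),
            coverage=c.get("coverage", 0),
            minor_fraction=c.get("minor_fraction"),
            flags=frozenset(c.get("flags", [])),
            no_call_reason=c.get("no_call_reason", "none"),
            y_dropin_allele=c.get("y_dropin_allele"),
        )
    return Profile(
        sample_id=data["sample_id"],
        calls=calls,
        sex_markers_present=bool(data["sex_markers_present"]),
    )


def write_profile_json(profile: Profile, path: str | Path) -> None:
    Path(path).write_text(canonical_json(profile_to_dict(profile)))


def read_profile_json(path: str | Path) -> Profile:
    return profile_from_dict(json.loads(Path(path).read_text()))


def canonical_json(obj) -> str:
    """Canonicalised JSON (sorted keys, stable layout) for byte-stable reruns."""
    return json.dumps(obj, sort_keys=True, indent=2) + "\n"
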
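"""Canonical miRNA seed-site counting on (circular) RNA targets and assembly
of the binding-evidence score tables.

The seed is nucleotides 2-7 of the mature miRNA (5'->3').  A site on the
target is a Watson-Crick reverse-complement match to the seed, optionally
extended by a match opposite miRNA position 8 (m8) and/or an adenosine on the
target opposite miRNA position 1 (the A1 anchor), giving the canonical
hierarchy:

    8mer     m8 match + seed match + A1 anchor
    7mer-m8  m8 match + seed match
    7mer-A1  seed match + A1 anchor
    6mer     seed match only

This counter deliberately replaces context-style site scoring: downstream
analysis only uses the *number* of sites, normalized by mature-sequence
length (MREs per kilobase).  Precomputed site-count tables can be supplied
instead of sequences.  circRNA targets are scanned as circles by default, so
sites spanning the back-splice junction are counted; positions are reported
0-based on the linearized mature sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import InteractionTable, SequenceSet

__all__ = [
    "SeedSiteHit",
    "SITE_TYPES",
    "find_seed_sites",
    "count_seed_sites",
    "binding_score",
    "binding_scores_from_sequences",
    "load_mir_gene_evidence",
    "mir_gene_evidence_table",
]

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# rank used by the --min-site-type floor: anything >= the floor is kept
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}


@dataclass(frozen=True)
class SeedSiteHit:
    """One seed-match site on a target.

    ``seed_start`` is the 0-based offset of the 6-nt seed-complementary core
    on the (linearized) target; ``position``/``length`` delimit the full site
    including any m8 extension, half-open, modulo target length for circular
    targets.
    """

    mirna_id: str
    target_id: str
    position: int
    length: int
    seed_start: int
    site_type: str


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def find_seed_sites(
    mirna_id: str,
    mirna_seq: str,
    target_id: str,
    target_seq: str,
    circular: bool = True,
) -> list[SeedSiteHit]:
    """All canonical seed sites for one miRNA on one target sequence.

    With ``circular=True`` the target is treated as a closed circle: the scan
    wraps across the junction and site positions are reported modulo the
    target length.  Targets shorter than 6 nt yield no sites.
    """
    mirna = mirna_seq.upper().replace("T", "U")
    target = target_seq.upper().replace("T", "U")
    if len(mirna) < 8:
        raise ValueError(f"miRNA {mirna_id!r} shorter than 8 nt; seed sites undefined")
    n = len(target)
    if n < 6:
        return []

    seed_rc = _revcomp(mirna[1:7])        # complements miRNA positions 2-7
    m8_rc = _COMPLEMENT[mirna[7]]         # target base pairing miRNA position 8

    # On the target 5'->3', the m8-pairing base sits immediately 5' of the
    # seed core and the A1 anchor immediately 3' of it.
    scan = target + target[:6] if circular else target
    max_start = (n - 1) if circular else (n - 6)

    hits: list[SeedSiteHit] = []
    start = scan.find(seed_rc)
    while 0 <= start <= max_start:
        if circular:
            m8_ok = scan[(start - 1) % n] == m8_rc if n >= 7 else False
            a1_pos = start + 6 if start + 6 < len(scan) else (start + 6) % n
            a1_ok = scan[a1_pos] == "A" if n >= 7 else False
        else:
            m8_ok = start >= 1 and scan[start - 1] == m8_rc
            a1_ok = start + 6 < n and scan[start + 6] == "A"
        if m8_ok and a1_ok:
            stype = "8mer"
        elif m8_ok:
            stype = "7mer-m8"
        elif a1_ok:
            stype = "7mer-A1"
        else:
            stype = "6mer"
        site_start = start - 1 if m8_ok else start
        length = 6 + (1 if m8_ok else 0) + (1 if a1_ok else 0)
        hits.append(
            SeedSiteHit(
                mirna_id=mirna_id,
                target_id=target_id,
                position=site_start % n if circular else site_start,
                length=length,
                seed_start=start % n if circular else start,
                site_type=stype,
            )
        )
        start = scan.find(seed_rc, start + 1)
    return hits


def count_seed_sites(
    hits: Iterable[SeedSiteHit], min_site_type: str = "6mer"
) -> int:
    """Number of hits at or above a site-type floor in the canonical hierarchy."""
    if min_site_type not in _SITE_RANK:
        raise ValueError(f"unknown site type {min_site_type!r}; choose from {SITE_TYPES}")
    floor = _SITE_RANK[min_site_type]
    return sum(1 for h in hits if _SITE_RANK[h.site_type] >= floor)


def binding_score(n_mre: int, mature_length_nt: int) -> float:
    """Length-normalized binding score: MREs per kilobase of mature sequence."""
    if mature_length_nt <= 0:
        raise ValueError("mature sequence length must be positive")
    if n_mre < 0:
        raise ValueError("site count must be non-negative")
    return n_mre * 1000.0 / mature_length_nt


def binding_scores_from_sequences(
    circ_seqs: SequenceSet,
    mir_seqs: SequenceSet,
    circular: bool = True,
    min_site_type: str = "6mer",
) -> pd.DataFrame:
    """Site counts and MREs/kb for every (circRNA, miRNA) sequence pair.

    Returns a tidy frame (circ_id, mir_id, n_mre, mature_length_nt,
    mre_per_kb) with one row per pair, zero-count pairs included.
    """
    rows = []
    for circ_id, circ_seq in circ_seqs.records.items():
        L = len(circ_seq)
        for mir_id, mir_seq in mir_seqs.records.items():
            hits = find_seed_sites(mir_id, mir_seq, circ_id, circ_seq, circular=circular)
            n = count_seed_sites(hits, min_site_type=min_site_type)
            rows.append((circ_id, mir_id, n, L, binding_score(n, L)))
    return pd.DataFrame(
        rows, columns=["circ_id", "mir_id", "n_mre", "mature_length_nt", "mre_per_kb"]
    )


def load_mir_gene_evidence(
    targetscan: Optional[pd.DataFrame] = None,
    mirtarbase: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Merge per-pair site-count and publication-count evidence tables.

    ``targetscan``: columns (mir_id, gene_id, n_sites) -- site counts, summed
    over duplicate rows (e.g. conserved + nonconserved families).
    ``mirtarbase``: columns (mir_id, gene_id, n_publications), likewise summed.
    The result is the outer union of pairs with absent evidence filled as 0;
    pairs with both counts 0 are dropped.
    """
    frames = []
    if targetscan is not None and len(targetscan):
        ts = targetscan[["mir_id", "gene_id", "n_sites"]].copy()
        if (ts["n_sites"] < 0).any():
            raise ValueError("negative site count in evidence table")
        ts = ts.groupby(["mir_id", "gene_id"], as_index=False)["n_sites"].sum()
        ts = ts.rename(columns={"n_sites": "n_mre_targetscan"})
        frames.append(ts)
    if mirtarbase is not None and len(mirtarbase):
        mtb = mirtarbase[["mir_id", "gene_id", "n_publications"]].copy()
        if (mtb["n_publications"] < 0).any():
            raise ValueError("negative publication count in evidence table")
        mtb = mtb.groupby(["mir_id", "gene_id"], as_index=False)["n_publications"].sum()
        mtb = mtb.rename(columns={"n_publications": "n_pubs_mirtarbase"})
        frames.append(mtb)
    if not frames:
        raise ValueError("at least one evidence table is required")
    merged = frames[0]
    for other in frames[1:]:
        merged = merged.merge(other, on=["mir_id", "gene_id"], how="outer")
    for col in ("n_mre_targetscan", "n_pubs_mirtarbase"):
        if col not in merged.columns:
            merged[col] = 0
        merged[col] = merged[col].fillna(0).astype(int)
    merged = merged[(merged["n_mre_targetscan"] > 0) | (merged["n_pubs_mirtarbase"] > 0)]
    return merged.sort_values(["mir_id", "gene_id"]).reset_index(drop=True)


def mir_gene_evidence_table(evidence: pd.DataFrame) -> InteractionTable:
    """Package merged evidence as a mir-gene InteractionTable with the two
    Pareto criteria (TargetScan site count, miRTarBase publication count)."""
    df = evidence.rename(columns={"mir_id": "source_id", "gene_id": "target_id"})
    return InteractionTable(
        edges=df[["source_id", "target_id", "n_mre_targetscan", "n_pubs_mirtarbase"]],
        edge_type="mir-gene",
    )
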
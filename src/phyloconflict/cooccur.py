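"""Fungal partner sharing between co-occurring and non-co-occurring
specimen pairs.

Given a table of lichen specimens (site, cyanobiont OTU, fungal partner),
for each ordered-agnostic OTU pair we enumerate specimen pairs — all cross
pairs for two distinct OTUs (n_A x n_B of them), all unordered within-OTU
pairs (n(n-1)/2) for a same-OTU row — split them by co-occurrence (same site
id, exact match) and count how many share a fungal partner.  Percentages are
truncated (floored) to two decimals, the convention of the published summary
table; full-precision values are carried alongside.

Elevated sharing among co-occurring pairs is the signature of local vertical
transmission of the cyanobiont rather than partner-driven divergence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

SPECIMEN_COLUMNS = ["specimen", "site", "otu", "partner"]


def truncate_percent(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator floored to two decimals
    (26/107 -> 24.29, where rounding would give 24.30)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return math.floor(100.0 * numerator / denominator * 100.0) / 100.0


@dataclass
class PartnerSharingRow:
    otu_pair: str
    total_pairs: int
    cooccurring_pairs: int
    noncooccurring_pairs: int
    cooccurring_sharing: int
    noncooccurring_sharing: int
    pct_cooccurring_sharing: Optional[float]
    pct_noncooccurring_sharing: Optional[float]
    # untruncated values for downstream statistics
    raw_pct_cooccurring: Optional[float] = None
    raw_pct_noncooccurring: Optional[float] = None


def _validate_specimens(specimens: pd.DataFrame, drop_unidentified: bool) -> pd.DataFrame:
    missing = [c for c in SPECIMEN_COLUMNS if c not in specimens.columns]
    if missing:
        raise ValueError(f"specimen table missing columns: {missing}")
    if specimens["specimen"].duplicated().any():
        raise ValueError("specimen ids must be unique")
    if drop_unidentified:
        specimens = specimens[specimens["partner"].notna() & (specimens["partner"] != "")]
    return specimens


def partner_sharing_table(specimens: pd.DataFrame,
                          otu_pairs: Sequence[tuple],
                          drop_unidentified: bool = True) -> list[PartnerSharingRow]:
    """One summary row per OTU pair.

    ``otu_pairs`` is a sequence of (otu_a, otu_b) label pairs; a pair with
    equal labels requests the within-OTU row.  Specimens without a fungal
    partner identification are excluded from all counts by default
    (``drop_unidentified=False`` keeps them in pair totals but they can
    never share).  Zero-denominator percentages are reported as None,
    not 0.
    """
    specimens = _validate_specimens(specimens, drop_unidentified)
    known = set(specimens["otu"])
    by_otu = {o: grp for o, grp in specimens.groupby("otu")}
    rows = []
    for a, b in otu_pairs:
        for otu in (a, b):
            if otu not in known:
                raise ValueError(f"unknown OTU label {otu!r}")
        rows.append(_one_row(by_otu, a, b))
    return rows


def _one_row(by_otu, a: str, b: str) -> PartnerSharingRow:
    ga = by_otu[a]
    if a == b:
        if len(ga) < 2:
            raise ValueError(f"within-OTU row for {a!r} needs at least 2 specimens")
        pairs = itertools.combinations(ga.itertuples(index=False), 2)
    else:
        gb = by_otu[b]
        pairs = itertools.product(ga.itertuples(index=False),
                                  gb.itertuples(index=False))
    co = nco = co_share = nco_share = 0
    for s1, s2 in pairs:
        share = _shares_partner(s1, s2)
        if s1.site == s2.site:
            co += 1
            co_share += share
        else:
            nco += 1
            nco_share += share
    return PartnerSharingRow(
        otu_pair=f"{a} and {b}",
        total_pairs=co + nco,
        cooccurring_pairs=co,
        noncooccurring_pairs=nco,
        cooccurring_sharing=co_share,
        noncooccurring_sharing=nco_share,
        pct_cooccurring_sharing=truncate_percent(co_share, co) if co else None,
        pct_noncooccurring_sharing=truncate_percent(nco_share, nco) if nco else None,
        raw_pct_cooccurring=100.0 * co_share / co if co else None,
        raw_pct_noncooccurring=100.0 * nco_share / nco if nco else None,
    )


def _shares_partner(s1, s2) -> bool:
    p1, p2 = s1.partner, s2.partner
    if p1 is None or p2 is None or (isinstance(p1, float) and math.isnan(p1)) \
            or (isinstance(p2, float) and math.isnan(p2)) or p1 == "" or p2 == "":
        return False
    return p1 == p2


def sharing_rows_to_frame(rows: Sequence[PartnerSharingRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def summary_from_counts(otu_pair: str, total: int, cooccurring: int,
                        co_sharing: int, nco_sharing: int) -> PartnerSharingRow:
    """Build a summary row from already-tabulated pair counts (e.g. the
    published table), recomputing the derived cells — the non-co-occurring
    count and both truncated percentages."""
    if cooccurring > total:
        raise ValueError("cooccurring pairs exceed total pairs")
    nco = total - cooccurring
    return PartnerSharingRow(
        otu_pair=otu_pair,
        total_pairs=total,
        cooccurring_pairs=cooccurring,
        noncooccurring_pairs=nco,
        cooccurring_sharing=co_sharing,
        noncooccurring_sharing=nco_sharing,
        pct_cooccurring_sharing=truncate_percent(co_sharing, cooccurring) if cooccurring else None,
        pct_noncooccurring_sharing=truncate_percent(nco_sharing, nco) if nco else None,
        raw_pct_cooccurring=100.0 * co_sharing / cooccurring if cooccurring else None,
        raw_pct_noncooccurring=100.0 * nco_sharing / nco if nco else None,
    )
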
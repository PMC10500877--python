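"""Window-based annotation of significant SNPs and cross-population overlap.

Features (genes or QTL) within 100 kb upstream or downstream of a
significant SNP are reported as positional candidates; the window is
symmetric physical distance, strand-agnostic, and inclusive at the
boundary. Overlap accounting reports, for every non-empty combination of
populations, the SNPs significant in exactly that combination.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 100_000


def read_gff(path, feature_types=None) -> pd.DataFrame:
    """Read a GFF/GTF-like feature table (1-based inclusive coordinates).

    Malformed lines are skipped with a logged warning. The feature id is
    taken from the first of ID=, gene_id, Name= found in the attributes
    column, falling back to the raw attribute string.
    """
    rows = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                n_bad += 1
                logger.warning("%s:%d: malformed feature line skipped",
                               path, lineno)
                continue
            seqid, source, ftype, start, end = parts[0], parts[1], parts[2], \
                parts[3], parts[4]
            try:
                start, end = int(start), int(end)
            except ValueError:
                n_bad += 1
                logger.warning("%s:%d: non-numeric coordinates skipped",
                               path, lineno)
                continue
            if feature_types is not None and ftype not in feature_types:
                continue
            rows.append(
                {
                    "seqid": seqid,
                    "source": source,
                    "type": ftype,
                    "start": start,
                    "end": end,
                    "feature_id": _feature_id(parts[8]),
                }
            )
    if n_bad:
        logger.warning("%s: skipped %d malformed lines", path, n_bad)
    return pd.DataFrame(rows,
                        columns=["seqid", "source", "type", "start", "end",
                                 "feature_id"])


def _feature_id(attributes: str) -> str:
    for key in ("ID=", "Name="):
        for field in attributes.split(";"):
            field = field.strip()
            if field.startswith(key):
                return field[len(key):].strip('"')
    for field in attributes.split(";"):
        field = field.strip()
        if field.startswith("gene_id"):
            return field.split(None, 1)[1].strip('"')
    return attributes.strip()


def annotate_windows(
    sig_snps: pd.DataFrame,
    features: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    source: str = "gene_gff",
) -> pd.DataFrame:
    """Features whose span intersects [pos - window, pos + window].

    ``sig_snps`` needs columns snp_id, chrom, pos_bp; ``features`` is the
    frame from :func:`read_gff`. Distance is 0 when the SNP lies inside the
    feature, otherwise the gap between the SNP and the nearest feature end;
    a gap of exactly ``window_bp`` still counts (inclusive boundary).
    """
    hits = []
    feats = features.copy()
    feats["chrom"] = pd.to_numeric(feats["seqid"], errors="coerce")
    for snp in sig_snps.itertuples(index=False):
        f = feats[feats["chrom"] == snp.chrom]
        if f.empty:
            continue
        start = f["start"].to_numpy()
        end = f["end"].to_numpy()
        dist = np.maximum(start - snp.pos_bp, 0) + \
            np.maximum(snp.pos_bp - end, 0)
        sel = dist <= window_bp
        for (_, row), d in zip(f[sel].iterrows(), dist[sel]):
            hits.append(
                {
                    "snp_id": snp.snp_id,
                    "feature_id": row["feature_id"],
                    "chrom": snp.chrom,
                    "feature_start": row["start"],
                    "feature_end": row["end"],
                    "distance_bp": int(d),
                    "source": source,
                }
            )
    return pd.DataFrame(hits,
                        columns=["snp_id", "feature_id", "chrom",
                                 "feature_start", "feature_end",
                                 "distance_bp", "source"])


def exclusive_overlaps(sig_sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive significant-SNP counts for every non-empty population subset.

    Each SNP is counted once, under the exact combination of populations in
    which it is significant; the exclusive counts therefore sum to the size
    of the union. The ``at_least`` column gives the marginal count of SNPs
    shared across >= k populations for k = subset size.
    """
    if len(sig_sets) < 2:
        raise ValueError("need at least two populations")
    pops = list(sig_sets)
    sets = {p: set(s) for p, s in sig_sets.items()}
    membership = {}
    for p, s in sets.items():
        for snp in s:
            membership.setdefault(snp, set()).add(p)

    rows = []
    for k in range(1, len(pops) + 1):
        for combo in combinations(pops, k):
            combo_set = frozenset(combo)
            count = sum(1 for m in membership.values() if m == combo_set)
            rows.append(
                {
                    "populations": "+".join(combo),
                    "k": k,
                    "exclusive_count": count,
                }
            )
    out = pd.DataFrame(rows)
    at_least = {
        k: sum(1 for m in membership.values() if len(m) >= k)
        for k in range(1, len(pops) + 1)
    }
    out["at_least_k"] = out["k"].map(at_least)
    return out
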
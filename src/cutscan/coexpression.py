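"""High-throughput Fisher-mode scanning for co-expression signatures.

Every gene in a matrix is scanned against a fixed binary status (for
example marker-low vs marker-high): the gene's own expression is
dichotomized at each percentile and the 2x2 association with the status is
scored with Fisher's exact test.  Genes whose optimal cut-off falls inside
a window around the status-defining cut-off (75 +/- 15% by default) form
the co-expression signature, sorted by optimal p-value.  Benjamini-Hochberg
q-values over per-gene optimal p are attached as a convenience column; the
optimal p remains the primary ranking.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import BinaryTrait, CohortTrait, align
from .scan import find_optimal, scan_cutoffs

__all__ = ["genome_scan", "filter_signature"]

log = logging.getLogger("cutscan")


def genome_scan(matrix, status: BinaryTrait, scan_range=(1, 99),
                keep_p_matrix: bool = False):
    """Fisher-mode scan of every gene against a fixed binary status.

    ``matrix`` is a mapping gene -> ``CohortTrait`` (as produced by
    :func:`cutscan.io.read_expression_matrix`).  Each gene is aligned to the
    status samples independently.  Returns a DataFrame indexed by gene with
    ``optimal_percent``, ``optimal_p``, ``q_value_bh``, ``n_valid_cuts`` and
    ``flag`` columns (optimal columns are NaN for all-invalid genes, e.g.
    constant expression); with ``keep_p_matrix`` a second DataFrame of
    per-cut p-values (genes x percents) is returned as well.
    """
    if len(matrix) == 0:
        raise ValueError("empty expression matrix")
    if status.group.min() == status.group.max():
        raise ValueError("status must contain both classes")
    rows = []
    p_rows = {}
    for i, (gene, trait) in enumerate(matrix.items()):
        if i and i % 1000 == 0:
            log.info("genome scan: %d genes done", i)
        trait_a, status_a = align(trait, status)
        scan = scan_cutoffs(trait_a, status_a, test_kind="fisher", scan_range=scan_range)
        n_valid = int(sum(r.valid for r in scan.records))
        constant = np.ptp(trait_a.values) == 0
        if n_valid == 0 or constant:
            rows.append({"gene": gene, "optimal_percent": np.nan, "optimal_p": np.nan,
                         "n_valid_cuts": 0 if constant else n_valid,
                         "flag": "constant" if constant else "all cuts invalid"})
        else:
            best = find_optimal(scan, search_range=scan_range)
            rows.append({"gene": gene, "optimal_percent": float(best.percent),
                         "optimal_p": best.p_value, "n_valid_cuts": n_valid,
                         "flag": ";".join(best.flags)})
        if keep_p_matrix:
            p_rows[gene] = pd.Series(scan.p_values, index=scan.percents)
    table = pd.DataFrame(rows).set_index("gene")
    ok = table["optimal_p"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(table.loc[ok, "optimal_p"], method="fdr_bh")[1]
    table["q_value_bh"] = q
    table = table[["optimal_percent", "optimal_p", "q_value_bh", "n_valid_cuts", "flag"]]
    if keep_p_matrix:
        return table, pd.DataFrame(p_rows).T
    return table


def filter_signature(table: pd.DataFrame, center: int = 75, window: int = 15,
                     gene_subset=None) -> pd.DataFrame:
    """Retain genes with optimal cut inside ``center +/- window``, best p first.

    ``gene_subset`` (e.g. a transcription-factor list) restricts the output
    to those genes.  Ties on p break on gene name; flagged all-invalid
    genes never pass.
    """
    if table.empty:
        raise ValueError("empty gene scan table")
    keep = table["optimal_percent"].between(center - window, center + window)
    sig = table[keep.fillna(False)]
    if gene_subset is not None:
        sig = sig[sig.index.isin(set(gene_subset))]
    # stable two-key sort: gene name first, then p, so p-ties break by name
    return sig.sort_index(kind="stable").sort_values("optimal_p", kind="stable")
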
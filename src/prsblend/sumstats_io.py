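"""Reading, validation, harmonization and QC of GWAS summary statistics.

A summary-statistics table is a :class:`pandas.DataFrame` with the
canonical columns ``SNP CHR BP A1 A2 AF B SE P N`` (A1 is the effect
allele; positions are 1-based). Files on disk are tab-separated text with
a header; arbitrary column names are supported through a *dialect*
mapping of canonical role -> file column name.

The proximal and adjunct studies are paired SNP-by-SNP with
:func:`harmonize`, which flips adjunct effects where the allele labels
are reversed and (optionally) removes strand-ambiguous A/T and C/G
pairs. SNPs present only in the proximal study are kept aside so they
can be passed through to the final score unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "AF", "B", "SE", "P", "N"]

#: roles that must be present in every input file
REQUIRED_ROLES = ["SNP", "CHR", "BP", "A1", "A2", "AF", "B", "SE", "P", "N"]

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SumstatsError(ValueError):
    """Raised for unrecoverable problems with a summary-statistics input."""


@dataclass
class QCReport:
    """Per-rule exclusion counts from a validation or filtering pass."""

    rule_counts: dict[str, int] = field(default_factory=dict)
    dropped: pd.DataFrame | None = None

    @property
    def n_dropped(self) -> int:
        return int(sum(self.rule_counts.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.rule_counts), "n_removed": list(self.rule_counts.values())}
        )


@dataclass
class AlignedPair:
    """Proximal/adjunct studies paired SNP-by-SNP after allele alignment.

    ``shared`` holds one row per SNP present in both studies, with the
    proximal columns suffixed ``_1`` and the (sign-aligned) adjunct
    columns suffixed ``_2``. ``proximal_only`` holds proximal rows with
    no adjunct counterpart. ``flipped`` flags shared rows whose adjunct
    effect was sign-flipped during alignment; ``exclusions`` counts rows
    dropped as strand-ambiguous or allele-irreconcilable.
    """

    shared: pd.DataFrame
    proximal_only: pd.DataFrame
    flipped: pd.Series
    exclusions: QCReport


def _normalize(df: pd.DataFrame, dialect: dict[str, str] | None) -> pd.DataFrame:
    if dialect:
        missing = [role for role, col in dialect.items() if col not in df.columns]
        if missing:
            raise SumstatsError(
                f"dialect maps roles {missing} to columns absent from the file"
            )
        df = df.rename(columns={col: role for role, col in dialect.items()})
    absent = [c for c in REQUIRED_ROLES if c not in df.columns]
    if absent:
        raise SumstatsError(f"missing required column(s) for role(s): {absent}")
    return df[CANONICAL_COLUMNS].copy()


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Drop rows violating the table invariants; report counts per rule.

    Enforced invariants: SE > 0, AF strictly inside (0, 1), p in (0, 1],
    single-nucleotide distinct alleles (indels and multi-allelic records
    are rejected), finite effect size, positive N, unique SNP ids.
    """
    df = df.copy()
    df["A1"] = df["A1"].astype(str).str.upper()
    df["A2"] = df["A2"].astype(str).str.upper()
    for col in ("AF", "B", "SE", "P", "N", "BP"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    rules: dict[str, pd.Series] = {
        "non_snp_allele": ~(
            df["A1"].isin(_VALID_ALLELES) & df["A2"].isin(_VALID_ALLELES)
        ),
        "identical_alleles": df["A1"] == df["A2"],
        "se_nonpositive": ~(df["SE"] > 0),
        "af_out_of_range": ~((df["AF"] > 0) & (df["AF"] < 1)),
        "pval_out_of_range": ~((df["P"] > 0) & (df["P"] <= 1)),
        "beta_nonfinite": ~np.isfinite(df["B"]),
        "n_nonpositive": ~(df["N"] > 0),
        "duplicate_snp_id": df["SNP"].duplicated(keep="first"),
    }
    bad = pd.Series(False, index=df.index)
    counts: dict[str, int] = {}
    for name, mask in rules.items():
        mask = mask.fillna(True) if mask.dtype == object else mask
        new = mask & ~bad
        counts[name] = int(new.sum())
        bad |= mask
    report = QCReport(rule_counts=counts, dropped=df[bad].copy())
    return df[~bad].reset_index(drop=True), report


def read_sumstats(
    path, dialect: dict[str, str] | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Read a whitespace/tab-separated summary-statistics file.

    Parameters
    ----------
    path
        Text file with a header row.
    dialect
        Optional mapping of canonical role (``"SNP"``, ``"B"``, ...) to
        the column name used in the file.

    Returns
    -------
    (table, report)
        Validated table in canonical column order, and the per-rule
        counts of dropped rows.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str})
    df = _normalize(df, dialect)
    df["SNP"] = df["SNP"].astype(str)
    df["CHR"] = df["CHR"].astype(str)
    table, report = validate_sumstats(df)
    if len(table) == 0:
        raise SumstatsError(f"no valid rows remain after validation of {path}")
    return table, report


def write_sumstats(table: pd.DataFrame, path, audit: bool = False) -> None:
    """Write a table as canonical TSV (lossless round-trip with read_sumstats).

    With ``audit=True`` any extra columns (lFDR, Q, Qpval, source, ...)
    are appended after the canonical ten.
    """
    cols = [c for c in CANONICAL_COLUMNS if c in table.columns]
    if audit:
        cols = cols + [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def _key(df: pd.DataFrame) -> pd.Series:
    return df["SNP"]


def harmonize(
    proximal: pd.DataFrame,
    adjunct: pd.DataFrame,
    drop_ambiguous: bool = True,
) -> AlignedPair:
    """Pair the two studies SNP-by-SNP, aligning adjunct effects to the
    proximal effect allele.

    For each SNP present in both studies the adjunct allele pair must
    equal the proximal pair either directly, reversed (effect allele
    swap: adjunct B is negated and AF reflected), or after strand
    complement (direct or reversed). Strand-ambiguous pairs (A/T, C/G)
    are removed when ``drop_ambiguous`` is set, since their orientation
    cannot be resolved from summary data. Irreconcilable allele pairs
    are dropped and counted, never silently kept.
    """
    prox = proximal.set_index(_key(proximal), drop=False)
    adj = adjunct.set_index(_key(adjunct), drop=False)

    common = prox.index.intersection(adj.index)
    proximal_only = prox.loc[prox.index.difference(common)].reset_index(drop=True)

    p = prox.loc[common]
    a = adj.loc[common]
    counts: dict[str, int] = {}

    ambiguous = pd.Series(
        [t in _AMBIGUOUS_PAIRS for t in zip(p["A1"], p["A2"])], index=common
    ) | pd.Series([t in _AMBIGUOUS_PAIRS for t in zip(a["A1"], a["A2"])], index=common)
    if drop_ambiguous:
        counts["strand_ambiguous"] = int(ambiguous.sum())
        keep = ~ambiguous
        p, a = p[keep], a[keep]
    else:
        counts["strand_ambiguous"] = 0

    a1p, a2p = p["A1"], p["A2"]
    a1a, a2a = a["A1"], a["A2"]
    a1ac = a1a.str.translate(_COMPLEMENT)
    a2ac = a2a.str.translate(_COMPLEMENT)

    same = (a1a == a1p) & (a2a == a2p)
    swapped = (a1a == a2p) & (a2a == a1p)
    same_c = (a1ac == a1p) & (a2ac == a2p) & ~same & ~swapped
    swapped_c = (a1ac == a2p) & (a2ac == a1p) & ~same & ~swapped
    match = same | swapped | same_c | swapped_c
    counts["allele_mismatch"] = int((~match).sum())

    p, a = p[match], a[match]
    flip = (swapped | swapped_c)[match]

    a = a.copy()
    a.loc[flip, "B"] = -a.loc[flip, "B"]
    a.loc[flip, "AF"] = 1.0 - a.loc[flip, "AF"]
    a["A1"] = p["A1"]
    a["A2"] = p["A2"]

    shared = pd.concat(
        [
            p.reset_index(drop=True).add_suffix("_1"),
            a.reset_index(drop=True)[["AF", "B", "SE", "P", "N"]].add_suffix("_2"),
        ],
        axis=1,
    )
    shared = shared.rename(
        columns={"SNP_1": "SNP", "CHR_1": "CHR", "BP_1": "BP", "A1_1": "A1", "A2_1": "A2"}
    )
    return AlignedPair(
        shared=shared,
        proximal_only=proximal_only,
        flipped=flip.reset_index(drop=True),
        exclusions=QCReport(rule_counts=counts),
    )


def qc_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Remove SNPs whose reported SE is inconsistent with AF and N.

    Per SNP two standard deviations are compared: the one implied by the
    summary statistics, ``sd_ss = 2 / sqrt(N * SE^2)``, and the one
    implied by the allele frequency under Hardy-Weinberg,
    ``sd_g = sqrt(2 * AF * (1 - AF))``. A SNP is removed when any of
    the following hold (the thresholds recommended for summary-statistic
    QC ahead of PRS construction):

    - ``sd_ss < 0.5 * sd_g``
    - ``sd_ss > sd_g + 0.1``
    - ``sd_ss < 0.1``
    - ``sd_g < 0.05``
    """
    for col in ("AF", "N"):
        if table[col].isna().any():
            raise SumstatsError(f"qc_filter requires non-missing {col}")
    sd_ss = 2.0 / np.sqrt(table["N"].to_numpy() * table["SE"].to_numpy() ** 2)
    sd_g = np.sqrt(2.0 * table["AF"].to_numpy() * (1.0 - table["AF"].to_numpy()))

    rules = {
        "sd_ss_below_half_sd_g": sd_ss < 0.5 * sd_g,
        "sd_ss_above_sd_g_plus_0.1": sd_ss > sd_g + 0.1,
        "sd_ss_below_0.1": sd_ss < 0.1,
        "sd_g_below_0.05": sd_g < 0.05,
    }
    bad = np.zeros(len(table), dtype=bool)
    counts = {}
    for name, mask in rules.items():
        counts[name] = int((mask & ~bad).sum())
        bad |= mask
    report = QCReport(rule_counts=counts, dropped=table[bad].copy())
    return table[~bad].reset_index(drop=True), report


def panel_retention_filter(
    table: pd.DataFrame,
    panel_ids: set[str],
    lfdr: np.ndarray,
    lfdr_threshold: float = 1.0,
) -> pd.DataFrame:
    """Keep SNPs in a reference panel OR with heterogeneity lFDR below a
    threshold.

    The panel clause implements the usual restriction of PRS weights to
    a well-imputed panel (e.g. HapMap3); the lFDR clause rescues SNPs
    outside the panel that carry evidence of between-study heterogeneity
    and therefore differentiate the two traits.
    """
    lfdr = np.asarray(lfdr, dtype=float)
    if len(lfdr) != len(table):
        raise SumstatsError(
            f"lfdr length {len(lfdr)} does not match table length {len(table)}"
        )
    in_panel = table["SNP"].isin(panel_ids).to_numpy()
    keep = in_panel | (lfdr < lfdr_threshold)
    return table[keep].reset_index(drop=True)
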
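"""Blended LD reference: correlations between blended effect estimates.

Summary-statistics PRS methods need an LD reference whose correlation
structure matches the sampling correlation of the effect estimates they
are given. The blended estimator mixes two studies with generally
different LD panels (different ancestries, or the same panel twice for
a cross-trait analysis), so neither input panel is correct on its own.

Writing the blended estimator at SNP i as a linear combination of the
two studies' marginal estimates,

    b_blend_i = a_i * b1_i + c_i * b2_i
    a_i = (1 - pi_i) + pi_i * w1_i/(w1_i + w2_i)
    c_i = pi_i * w2_i/(w1_i + w2_i),          w = 1/se^2,

its cross-SNP covariance follows from the per-study sampling
covariances Cov(bk_i, bk_j) = Rk_ij * sek_i * sek_j and the
shared-subject cross-study term rho * Rbar_ij * se1_i * se2_j, with
Rbar = (R1 + R2)/2 standing in for the unobservable cross-panel LD
(exactly zero contribution in the cross-ancestry case, where rho = 0):

    Cov_ij = a_i a_j R1_ij s1_i s1_j + c_i c_j R2_ij s2_i s2_j
             + rho * (a_i c_j + a_j c_i) * Rbar_ij s1_i s2_j-terms

The covariance is normalized to a correlation matrix and repaired to
positive semi-definite by eigenvalue clipping.

On disk an :class:`LDBlockSet` is a manifest TSV (block_id, chrom,
start, end with 0-based half-open intervals, n_snps) plus one dense
little-endian float64 matrix file per block with a 16-byte header
(magic ``LDBK``, version, n_snps) and a SNP-id sidecar per block.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_MAGIC = b"LDBK"
_VERSION = 1


@dataclass
class LDBlock:
    """One LD block: ordered SNP ids and their correlation matrix."""

    block_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    snp_ids: list[str]
    matrix: np.ndarray

    def validate(self, atol: float = 1e-6) -> None:
        m = self.matrix
        if m.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError(f"block {self.block_id}: matrix/SNP-list size mismatch")
        if not np.allclose(m, m.T, atol=atol):
            raise ValueError(f"block {self.block_id}: matrix not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=atol):
            raise ValueError(f"block {self.block_id}: diagonal not unit")
        if np.any(np.abs(m) > 1.0 + atol):
            raise ValueError(f"block {self.block_id}: |entries| exceed 1")


@dataclass
class LDBlockSet:
    """Ordered collection of LD blocks with a manifest."""

    blocks: list[LDBlock] = field(default_factory=list)

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def snp_ids(self) -> list[str]:
        return [s for b in self.blocks for s in b.snp_ids]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block_id": [b.block_id for b in self.blocks],
                "chrom": [b.chrom for b in self.blocks],
                "start": [b.start for b in self.blocks],
                "end": [b.end for b in self.blocks],
                "n_snps": [len(b.snp_ids) for b in self.blocks],
            }
        )

    def write(self, directory) -> None:
        """Write manifest TSV + per-block binary matrices and SNP lists."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.manifest().to_csv(directory / "manifest.tsv", sep="\t", index=False)
        for b in self.blocks:
            with open(directory / f"{b.block_id}.ld", "wb") as fh:
                fh.write(struct.pack("<4sii", _MAGIC, _VERSION, len(b.snp_ids)))
                fh.write(np.ascontiguousarray(b.matrix, dtype="<f8").tobytes())
            (directory / f"{b.block_id}.snps").write_text(
                "\n".join(b.snp_ids) + "\n"
            )

    @classmethod
    def read(cls, directory) -> "LDBlockSet":
        directory = Path(directory)
        manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
        blocks = []
        for row in manifest.itertuples(index=False):
            with open(directory / f"{row.block_id}.ld", "rb") as fh:
                magic, version, n = struct.unpack("<4sii", fh.read(12))
                if magic != _MAGIC:
                    raise ValueError(f"{row.block_id}.ld: bad magic {magic!r}")
                mat = np.frombuffer(fh.read(8 * n * n), dtype="<f8").reshape(n, n)
            snps = (directory / f"{row.block_id}.snps").read_text().split()
            block = LDBlock(
                block_id=str(row.block_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                snp_ids=snps,
                matrix=mat.copy(),
            )
            block.validate()
            blocks.append(block)
        return cls(blocks=blocks)


def _psd_repair(corr: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues to zero and re-normalize the diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= -tol:
        out = corr
    else:
        vals = np.clip(vals, 0.0, None)
        out = (vecs * vals) @ vecs.T
        d = np.sqrt(np.clip(np.diag(out), 1e-300, None))
        out = out / np.outer(d, d)
    out = np.clip((out + out.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return out


def blend_ld_block(
    R1: np.ndarray,
    R2: np.ndarray,
    se1: np.ndarray,
    se2: np.ndarray,
    lfdr: np.ndarray,
    rho: float = 0.0,
) -> np.ndarray:
    """Correlation matrix of the blended effect estimates for one block.

    ``R1``/``R2`` are the proximal/adjunct SNP-SNP correlation matrices
    over the same ordered SNPs; ``se1``/``se2``/``lfdr`` the per-SNP
    standard errors and blending weights; ``rho`` the scalar overlap
    correlation. Returns a symmetric, unit-diagonal, PSD matrix.
    """
    R1 = np.asarray(R1, float)
    R2 = np.asarray(R2, float)
    se1, se2 = np.asarray(se1, float), np.asarray(se2, float)
    pi = np.asarray(lfdr, float)
    n = len(se1)
    if R1.shape != (n, n) or R2.shape != (n, n) or len(se2) != n or len(pi) != n:
        raise ValueError("SNP order/length mismatch between panels and vectors")

    if np.all(pi == 0.0):
        # pure proximal limit: the blended estimator is b1, so its LD is
        # exactly the proximal panel
        return R1.copy()

    w1, w2 = 1.0 / se1**2, 1.0 / se2**2
    a = (1.0 - pi) + pi * w1 / (w1 + w2)  # loading on study 1
    c = pi * w2 / (w1 + w2)  # loading on study 2

    s1a = a * se1
    s2c = c * se2
    cov = np.outer(s1a, s1a) * R1 + np.outer(s2c, s2c) * R2
    if rho != 0.0:
        rbar = 0.5 * (R1 + R2)
        cross = np.outer(a * se1, c * se2)
        cov = cov + rho * rbar * (cross + cross.T)

    d = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    corr = cov / np.outer(d, d)
    return _psd_repair(corr)


def blend_ld_genome(
    panel1: LDBlockSet,
    panel2: LDBlockSet,
    blended,
    rho: float = 0.0,
) -> tuple[LDBlockSet, pd.DataFrame]:
    """Blend two LD panels genome-wide, block by block.

    ``blended`` is a :class:`prsblend.blending.BlendedStats` (or its
    table) carrying per-SNP SE columns for both studies and the lFDR:
    the required columns are ``SNP``, ``lFDR``, ``SE_1``, ``SE_2`` for
    blended rows; passthrough rows (``source == 'proximal_passthrough'``
    or missing lFDR) keep the proximal panel's rows/columns.

    Blocks are matched by ``block_id`` between the two panels and
    intersected to their common SNPs. Returns the blended panel and a
    per-block report of SNP losses.
    """
    table = getattr(blended, "table", blended)
    info = table.set_index("SNP")
    p2 = {b.block_id: b for b in panel2.blocks}

    out_blocks: list[LDBlock] = []
    report_rows = []
    for b1 in panel1.blocks:
        b2 = p2.get(b1.block_id)
        if b2 is None:
            raise ValueError(f"block {b1.block_id} missing from the adjunct panel")
        in_table = [s for s in b1.snp_ids if s in info.index]
        snps2 = set(b2.snp_ids)

        keep, passthrough = [], []
        for s in in_table:
            row = info.loc[s]
            is_pass = (
                ("source" in info.columns and row.get("source") == "proximal_passthrough")
                or ("lFDR" in info.columns and pd.isna(row.get("lFDR")))
                or s not in snps2
            )
            (passthrough if is_pass else keep).append(s)

        snps = keep + passthrough  # blended SNPs first, then proximal passthrough
        if not snps:
            report_rows.append((b1.block_id, len(b1.snp_ids), 0, 0))
            continue
        idx1 = [b1.snp_ids.index(s) for s in snps]
        sub1 = b1.matrix[np.ix_(idx1, idx1)]
        k = len(keep)
        mat = sub1.copy()
        if k > 0:
            idx2 = [b2.snp_ids.index(s) for s in keep]
            sub2 = b2.matrix[np.ix_(idx2, idx2)]
            se1 = info.loc[keep, "SE_1"].to_numpy(float)
            se2 = info.loc[keep, "SE_2"].to_numpy(float)
            pi = info.loc[keep, "lFDR"].to_numpy(float)
            mat[:k, :k] = blend_ld_block(sub1[:k, :k], sub2, se1, se2, pi, rho=rho)
        mat = _psd_repair(mat)
        out_blocks.append(
            LDBlock(
                block_id=b1.block_id,
                chrom=b1.chrom,
                start=b1.start,
                end=b1.end,
                snp_ids=snps,
                matrix=mat,
            )
        )
        report_rows.append((b1.block_id, len(b1.snp_ids), k, len(passthrough)))

    report = pd.DataFrame(
        report_rows, columns=["block_id", "n_snps_panel1", "n_blended", "n_passthrough"]
    )
    return LDBlockSet(blocks=out_blocks), report
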
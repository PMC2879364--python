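"""Tabular input/output: SNP tables, population-frequency files, region
calls, and genome-browser tracks.

Input SNP tables are tab-delimited BeadStudio-style exports with one row
per SNP; default column headers are the BeadStudio names ("B Allele Freq",
"Log R Ratio") and can be remapped for other upstreams. Input positions
are 1-based. Region calls are written 0-based half-open (BED convention):
start = first SNP position - 1, end = last SNP position.

Browser tracks: SGR files (chrom, position, value) carry the raw BAF and
LRR signals; WIG files (variableStep) carry the decoded copy number and
allelic imbalance.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .hmm import CNVRegion

__all__ = [
    "DEFAULT_COLUMNS",
    "read_snp_table",
    "read_pb_file",
    "write_snp_table",
    "write_regions",
    "read_regions",
    "write_tracks",
    "labels_from_regions",
]

logger = logging.getLogger(__name__)

#: canonical name -> default input header (BeadStudio export)
DEFAULT_COLUMNS: dict[str, str] = {
    "name": "Name",
    "chrom": "Chr",
    "position": "Position",
    "baf": "B Allele Freq",
    "lrr": "Log R Ratio",
}

_AUTOSOMES = {str(i) for i in range(1, 23)}


def _norm_chrom(c: str) -> str:
    c = str(c).strip()
    return c[3:] if c.lower().startswith("chr") else c


def read_snp_table(path: str | Path,
                   columns: Mapping[str, str] | None = None,
                   pb: Mapping[str, float] | None = None,
                   include_xy: bool = False) -> pd.DataFrame:
    """Load a per-SNP table into the canonical frame.

    Returns columns name/chrom/position/baf/lrr/pb, sorted by (chrom,
    position), BAF clipped to [0,1]. Rows with missing BAF or LRR are
    dropped (count logged); non-autosomal rows are dropped unless
    ``include_xy``. ``pb`` maps SNP name -> population B-allele frequency
    (default 0.5 for every SNP not in the map).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={colmap["chrom"]: str})
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    df = df[["name", "chrom", "position", "baf", "lrr"]].copy()

    n0 = len(df)
    df = df.dropna(subset=["baf", "lrr"])
    if len(df) < n0:
        logger.warning("dropped %d SNP(s) with missing BAF/LRR", n0 - len(df))

    df["chrom"] = df["chrom"].map(_norm_chrom)
    if not include_xy:
        n1 = len(df)
        df = df[df["chrom"].isin(_AUTOSOMES)]
        if len(df) < n1:
            logger.info("dropped %d non-autosomal SNP(s)", n1 - len(df))
    if len(df) == 0:
        raise ValueError(f"no usable SNPs in {path}")

    df["position"] = df["position"].astype(np.int64)
    df["baf"] = df["baf"].astype(float).clip(0.0, 1.0)
    df["lrr"] = df["lrr"].astype(float)
    df["pb"] = (df["name"].map(lambda n: pb.get(n, 0.5)) if pb
                else 0.5)
    key = df["chrom"].map(lambda c: (0, int(c)) if c.isdigit() else (1, c))
    df = df.assign(_key=key).sort_values(["_key", "position"], kind="stable")
    df = df.drop(columns="_key").reset_index(drop=True)
    dup = df.duplicated(subset=["chrom", "position"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} SNP(s) share a (chrom, position); positions "
            "must be strictly increasing within each chromosome")
    return df


def write_snp_table(snps: pd.DataFrame, path: str | Path,
                    header_comment: str | None = None) -> None:
    """Write the canonical frame back to the BeadStudio-style format."""
    out = snps[["name", "chrom", "position", "baf", "lrr"]].copy()
    out.columns = [DEFAULT_COLUMNS[c] for c in ["name", "chrom", "position",
                                                "baf", "lrr"]]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_pb_file(path: str | Path) -> dict[str, float]:
    """Two-column (SNP name, pB) file -> lookup dict.

    Malformed lines and out-of-range frequencies are skipped with a
    warning; on duplicate names the last entry wins.
    """
    out: dict[str, float] = {}
    n_bad = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                n_bad += 1
                continue
            name, val = parts
            try:
                f = float(val)
            except ValueError:
                if lineno == 1:     # header row
                    continue
                n_bad += 1
                continue
            if not 0.0 <= f <= 1.0:
                n_bad += 1
                continue
            if name in out:
                logger.warning("duplicate SNP %r in %s; keeping last", name, path)
            out[name] = f
    if n_bad:
        logger.warning("skipped %d malformed line(s) in %s", n_bad, path)
    return out


# ---------------------------------------------------------------------------
# region calls

_REGION_COLS = ("chrom", "start", "end", "state", "cn", "ai", "n_snps")


def write_regions(regions: Iterable[CNVRegion], path: str | Path,
                  header_comment: str | None = None) -> None:
    """BED-like region call table (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_REGION_COLS) + "\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_pos - 1}\t{r.end_pos}\t{r.state}"
                     f"\t{r.copy_number}\t{r.allelic_imbalance:.6f}"
                     f"\t{r.n_snps}\n")


def read_regions(path: str | Path) -> list[CNVRegion]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if list(df.columns) != list(_REGION_COLS):
        raise ValueError(f"unexpected region table columns in {path}: "
                         f"{list(df.columns)}")
    return [CNVRegion(chrom=row.chrom, start_pos=int(row.start) + 1,
                      end_pos=int(row.end), state=row.state,
                      n_snps=int(row.n_snps), copy_number=int(row.cn),
                      allelic_imbalance=float(row.ai))
            for row in df.itertuples(index=False)]


def labels_from_regions(snps: pd.DataFrame,
                        regions: Iterable[CNVRegion]) -> pd.DataFrame:
    """Per-SNP state/cn/ai frame by interval lookup into region calls."""
    by_chrom: dict[str, list[CNVRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    states = np.empty(len(snps), dtype=object)
    cn = np.zeros(len(snps), dtype=int)
    ai = np.zeros(len(snps), dtype=float)
    pos_all = np.asarray(snps["position"])
    chrom_all = np.asarray(snps["chrom"].astype(str))
    for chrom, regs in by_chrom.items():
        regs = sorted(regs, key=lambda r: r.start_pos)
        starts = np.array([r.start_pos for r in regs])
        ends = np.array([r.end_pos for r in regs])
        sel = np.flatnonzero(chrom_all == chrom)
        idx = np.searchsorted(starts, pos_all[sel], side="right") - 1
        for k, i in zip(sel, idx):
            if i < 0 or pos_all[k] > ends[i]:
                raise ValueError(
                    f"SNP at {chrom}:{pos_all[k]} not covered by any region")
            r = regs[i]
            states[k], cn[k], ai[k] = r.state, r.copy_number, r.allelic_imbalance
    if any(s is None for s in states):
        raise ValueError("some SNPs fall on chromosomes absent from the regions")
    return pd.DataFrame({"state": states, "cn": cn, "ai": ai})


# ---------------------------------------------------------------------------
# browser tracks

def _write_sgr(path: Path, snps: pd.DataFrame, column: str) -> None:
    with open(path, "w") as fh:
        for chrom, pos, val in zip(snps["chrom"], snps["position"], snps[column]):
            fh.write(f"chr{chrom}\t{pos}\t{val:.6f}\n")


def _write_wig(path: Path, snps: pd.DataFrame, values: np.ndarray,
               track_name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track_name}"\n')
        for chrom, grp in snps.groupby("chrom", sort=False):
            fh.write(f"variableStep chrom=chr{chrom}\n")
            for pos, val in zip(grp["position"], values[grp.index]):
                fh.write(f"{pos}\t{val:.6f}\n")


def write_tracks(snps: pd.DataFrame, labels: pd.DataFrame,
                 out_dir: str | Path, prefix: str = "sample") -> list[Path]:
    """Write BAF/LRR SGR tracks and CN/AI WIG tracks for a decoded sample.

    ``labels`` is the per-SNP frame from :func:`labels_from_regions` (or a
    truth table) aligned with ``snps``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snps = snps.reset_index(drop=True)
    labels = labels.reset_index(drop=True)
    paths = []
    for col in ("baf", "lrr"):
        p = out_dir / f"{prefix}.{col}.sgr"
        _write_sgr(p, snps, col)
        paths.append(p)
    for col, name in (("cn", "copy_number"), ("ai", "allelic_imbalance")):
        p = out_dir / f"{prefix}.{col}.wig"
        _write_wig(p, snps, np.asarray(labels[col], dtype=float), name)
        paths.append(p)
    return paths
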
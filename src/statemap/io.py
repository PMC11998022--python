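"""File formats: Matrix Market count matrices with TSV sidecars, BED
interval sets, compressed-binary matrices with JSON manifests, and flat
key-value configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from ._types import CellTable, NormalizedMatrix, PeakMatrix, PeakSet


def write_matrix(obj: CellTable | PeakMatrix, prefix) -> None:
    """Write counts as <prefix>.mtx with cells.tsv / features.tsv sidecars."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, CellTable):
        sio.mmwrite(str(prefix) + ".mtx", obj.counts)
        obj.cell_meta.to_csv(str(prefix) + ".cells.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": obj.gene_names,
                      "mito": obj.mito if obj.mito is not None
                      else np.zeros(len(obj.gene_names), bool)}
                     ).to_csv(str(prefix) + ".features.tsv", sep="\t", index=False)
    elif isinstance(obj, PeakMatrix):
        sio.mmwrite(str(prefix) + ".mtx", obj.counts)
        with open(str(prefix) + ".manifest.json", "w") as fh:
            json.dump({"level": obj.level, "normalized": obj.normalized}, fh)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_matrix(prefix) -> CellTable | PeakMatrix:
    """Read a matrix written by :func:`write_matrix`; the sidecars present
    determine whether a CellTable or PeakMatrix comes back."""
    prefix = str(prefix)
    mtx = Path(prefix + ".mtx")
    if not mtx.exists():
        raise FileNotFoundError(f"missing matrix file {mtx}")
    counts = sp.csr_matrix(sio.mmread(str(mtx)))
    cells = Path(prefix + ".cells.tsv")
    feats = Path(prefix + ".features.tsv")
    if cells.exists() or feats.exists():
        if not cells.exists():
            raise FileNotFoundError(f"missing sidecar {cells}")
        if not feats.exists():
            raise FileNotFoundError(f"missing sidecar {feats}")
        meta = pd.read_csv(cells, sep="\t")
        fdf = pd.read_csv(feats, sep="\t")
        if counts.shape != (len(meta), len(fdf)):
            raise ValueError(
                f"matrix shape {counts.shape} does not match sidecars "
                f"({len(meta)} cells, {len(fdf)} features)"
            )
        mito = fdf["mito"].to_numpy(bool) if "mito" in fdf else None
        return CellTable(counts, meta, fdf["gene"].to_numpy(object), mito=mito)
    manifest = Path(prefix + ".manifest.json")
    level, normalized = "cell", False
    if manifest.exists():
        d = json.loads(manifest.read_text())
        level, normalized = d.get("level", "cell"), d.get("normalized", False)
    return PeakMatrix(counts, level=level, normalized=normalized)


def write_bed(ps: PeakSet, path, signal: np.ndarray | None = None) -> None:
    """BED6 (+GC fraction in column 7, +signal in column 8 when present)."""
    df = pd.DataFrame({
        "chrom": ps.chrom, "start": ps.start, "end": ps.end,
        "name": [f"region_{i}" for i in range(len(ps))],
        "score": 0, "strand": ".",
    })
    if ps.gc is not None:
        df["gc"] = ps.gc
    sig = signal if signal is not None else getattr(ps, "signal", None)
    if sig is not None:
        if ps.gc is None:
            df["gc"] = -1.0
        df["signal"] = sig
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> PeakSet:
    """Read BED3/BED6 (+optional GC column 7, signal column 8)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {ln}: fewer than 3 BED columns")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"line {ln}: start >= end ({start} >= {end})")
            rows.append((parts[0], start, end,
                         float(parts[6]) if len(parts) > 6 else np.nan,
                         float(parts[7]) if len(parts) > 7 else np.nan))
    if not rows:
        raise ValueError(f"no intervals in {path}")
    chrom, start, end, gc, sig = map(np.array, zip(*rows))
    gc_arr = None if np.all(np.isnan(gc.astype(float))) else gc.astype(float)
    if gc_arr is not None and np.any(gc_arr < 0):
        gc_arr = None
    ps = PeakSet(chrom.astype(object), start.astype(int), end.astype(int), gc=gc_arr)
    sig = sig.astype(float)
    if not np.all(np.isnan(sig)):
        ps.signal = sig
    return ps


def write_normalized(nm: NormalizedMatrix, prefix) -> None:
    prefix = str(prefix)
    np.savez_compressed(prefix + ".npz", values=nm.values,
                        gene_names=np.asarray(nm.gene_names, dtype=str)
                        if nm.gene_names is not None else np.array([]))
    with open(prefix + ".manifest.json", "w") as fh:
        json.dump({"shape": list(nm.values.shape),
                   "scale_factor": nm.scale_factor,
                   "pseudo_count": nm.pseudo_count}, fh)


def read_normalized(prefix) -> NormalizedMatrix:
    prefix = str(prefix)
    with np.load(prefix + ".npz", allow_pickle=False) as z:
        values = z["values"]
        genes = z["gene_names"]
    d = json.loads(Path(prefix + ".manifest.json").read_text())
    return NormalizedMatrix(values, scale_factor=d["scale_factor"],
                            pseudo_count=d["pseudo_count"],
                            gene_names=genes.astype(object) if genes.size else None)


def read_config(path) -> dict:
    """Flat key = value config; values parsed as int/float/bool when possible."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            out[key] = _parse_value(val)
    return out


def _parse_value(v: str):
    low = v.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for k in sorted(cfg):
            fh.write(f"{k} = {cfg[k]}\n")
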
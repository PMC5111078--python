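"""Readers and writers for the pipeline's plain-text formats.

Formats (all coordinates in decimal degrees, WGS84, written at 6 decimals;
marker indexes 0-based inclusive):

* **Q matrix** — whitespace-delimited admixture proportions, one row per
  individual, K columns, 6 decimals (the de-facto ADMIXTURE ``.Q`` dialect).
  Rows whose sum deviates from 1 by at most 0.01 are renormalised; larger
  deviations, negatives and ragged rows are parse errors with line numbers.
* **panel CSV** — header ``population,subpopulation,lat,lon,q_1..q_K``; one
  row per member; rows grouped into populations/subpopulations.
* **genotype TSV** — rows = individuals (first column ``id``), columns =
  loci, values 0/1/2/NA.
* **ancestral frequency CSV** — header ``component,f_1..f_L``; one row per
  ancestral component.
* **haplogroup CSV** — header ``population,haplogroup,count``.
* **IBD segment TSV** — header ``id1 id2 chrom start_idx end_idx cM score``.
* **truth CSV** — header ``id,lat,lon[,region]``.

Every writer can attach a JSON metadata sidecar (`<path>.meta.json`) with
the seed, parameters and package version that produced the artifact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError
from .gps import PredictionResult, ReferencePopulation, _check_coordinate
from .ibd import IBDSegment
from .world import MISSING, SyntheticWorld

__all__ = [
    "read_q_matrix",
    "write_q_matrix",
    "read_panel",
    "write_panel",
    "read_genotypes",
    "write_genotypes",
    "read_frequencies",
    "write_frequencies",
    "read_haplogroup_counts",
    "read_ibd_segments",
    "write_ibd_segments",
    "read_truth",
    "write_truth",
    "write_predictions",
    "write_world",
    "write_sidecar",
]


def write_sidecar(path, metadata: Mapping) -> Path:
    """Write `<path>.meta.json` describing how an artifact was produced."""
    from . import __version__

    side = Path(str(path) + ".meta.json")
    payload = {"biogps_version": __version__, **metadata}
    side.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return side


# ---------------------------------------------------------------------------
# Q matrices


def read_q_matrix(path) -> np.ndarray:
    """Read a whitespace-delimited Q matrix; returns (n, K) simplex rows."""
    rows: list[list[float]] = []
    ncols = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            vals = [float(tok) for tok in line.split()]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric entry ({exc})") from None
        if ncols is None:
            ncols = len(vals)
        elif len(vals) != ncols:
            raise ParseError(f"{path}:{lineno}: ragged row ({len(vals)} columns, expected {ncols})")
        if any(v < 0 for v in vals):
            raise ParseError(f"{path}:{lineno}: negative admixture proportion")
        s = sum(vals)
        if abs(s - 1.0) > 0.01:
            raise ParseError(f"{path}:{lineno}: row sums to {s:.4f}, outside 1 +/- 0.01")
        rows.append([v / s for v in vals])
    if not rows:
        raise ParseError(f"{path}: empty Q matrix")
    return np.asarray(rows, dtype=float)


def write_q_matrix(Q, path) -> Path:
    path = Path(path)
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    with path.open("w") as fh:
        for row in Q:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# reference panels


def read_panel(path) -> list[ReferencePopulation]:
    """Read a panel CSV into grouped :class:`ReferencePopulation` objects."""
    df = pd.read_csv(path, dtype={"population": str, "subpopulation": str})
    qcols = [c for c in df.columns if c.startswith("q_")]
    required = {"population", "lat", "lon"}
    if not required.issubset(df.columns) or not qcols:
        raise ParseError(f"{path}: panel CSV needs population, lat, lon and q_* columns")
    if "subpopulation" not in df.columns:
        df["subpopulation"] = None
    df["subpopulation"] = df["subpopulation"].where(pd.notna(df["subpopulation"]), None)
    if "id" not in df.columns:
        df["id"] = [f"row{i}" for i in range(len(df))]
    panel = []
    for (name, sub), grp in df.groupby(["population", "subpopulation"], dropna=False, sort=True):
        lat, lon = float(grp["lat"].iloc[0]), float(grp["lon"].iloc[0])
        try:
            _check_coordinate((lat, lon))
        except DomainError as exc:
            raise ParseError(f"{path}: population {name!r}: {exc}") from None
        Q = grp[qcols].to_numpy(dtype=float)
        if np.any(Q < 0) or np.any(np.abs(Q.sum(axis=1) - 1.0) > 0.01):
            raise ParseError(f"{path}: population {name!r}: invalid admixture rows")
        Q = Q / Q.sum(axis=1, keepdims=True)
        panel.append(
            ReferencePopulation(
                name=str(name),
                location=(lat, lon),
                members=Q,
                member_ids=[str(i) for i in grp["id"]],
                subpopulation=None if sub is None or (isinstance(sub, float) and np.isnan(sub)) else str(sub),
            )
        )
    return panel


def write_panel(panel: Sequence[ReferencePopulation], path) -> Path:
    path = Path(path)
    rows = []
    for pop in panel:
        for i in range(pop.n_members):
            row = {
                "population": pop.name,
                "subpopulation": pop.subpopulation,
                "lat": round(pop.location[0], 6),
                "lon": round(pop.location[1], 6),
                "id": pop.member_ids[i],
            }
            row.update({f"q_{k + 1}": round(float(v), 6) for k, v in enumerate(pop.members[i])})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# genotypes and ancestral frequencies


def read_genotypes(path) -> tuple[list[str], np.ndarray]:
    """Read a genotype TSV; returns (ids, (n, L) int8 matrix with MISSING=-1)."""
    df = pd.read_csv(path, sep="\t", index_col="id")
    X = df.to_numpy(dtype=float)
    bad = ~np.isnan(X) & ~np.isin(X, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ParseError(f"{path}: invalid genotype value {X[i, j]!r} at row {i + 1}, locus {j + 1}")
    G = np.where(np.isnan(X), MISSING, X).astype(np.int8)
    return [str(i) for i in df.index], G


def write_genotypes(ids: Sequence[str], G, path) -> Path:
    path = Path(path)
    G = np.atleast_2d(np.asarray(G))
    df = pd.DataFrame(
        np.where(G == MISSING, np.nan, G),
        index=pd.Index(ids, name="id"),
        columns=[f"L{j}" for j in range(G.shape[1])],
    )
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")
    return path


def read_frequencies(path) -> tuple[list[str], np.ndarray]:
    """Read an ancestral-frequency CSV; returns (component labels, (K, L) matrix)."""
    df = pd.read_csv(path, index_col="component")
    F = df.to_numpy(dtype=float)
    if np.any((F < 0) | (F > 1)):
        raise ParseError(f"{path}: allele frequencies must lie in [0, 1]")
    return [str(i) for i in df.index], F


def write_frequencies(labels: Sequence[str], F, path) -> Path:
    path = Path(path)
    F = np.atleast_2d(np.asarray(F, dtype=float))
    pd.DataFrame(
        F, index=pd.Index(labels, name="component"), columns=[f"f_{j + 1}" for j in range(F.shape[1])]
    ).to_csv(path, float_format="%.6f")
    return path


# ---------------------------------------------------------------------------
# haplogroups, IBD, truth, predictions


def read_haplogroup_counts(path, marker: str = "mtDNA"):
    from .haplogroups import HaplogroupTable

    df = pd.read_csv(path)
    if not {"population", "haplogroup", "count"}.issubset(df.columns):
        raise ParseError(f"{path}: haplogroup CSV needs population, haplogroup, count columns")
    return HaplogroupTable(df, marker=marker)


def read_ibd_segments(path) -> list[IBDSegment]:
    df = pd.read_csv(path, sep="\t")
    needed = {"id1", "id2", "chrom", "start_idx", "end_idx", "cM", "score"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: IBD TSV needs columns {sorted(needed)}")
    return [
        IBDSegment(
            pair=(str(r.id1), str(r.id2)),
            chromosome=str(r.chrom),
            start=int(r.start_idx),
            end=int(r.end_idx),
            length_cm=float(r.cM),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


def write_ibd_segments(segments: Iterable[IBDSegment], path) -> Path:
    path = Path(path)
    rows = [
        {
            "id1": s.pair[0],
            "id2": s.pair[1],
            "chrom": s.chromosome,
            "start_idx": s.start,
            "end_idx": s.end,
            "cM": round(s.length_cm, 6),
            "score": s.score,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=["id1", "id2", "chrom", "start_idx", "end_idx", "cM", "score"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    if not {"id", "lat", "lon"}.issubset(df.columns):
        raise ParseError(f"{path}: truth CSV needs id, lat, lon columns")
    return df.set_index("id")


def write_truth(ids: Sequence[str], coords, path, regions: Mapping[str, str] | None = None) -> Path:
    path = Path(path)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    df = pd.DataFrame(
        {"id": ids, "lat": np.round(coords[:, 0], 6), "lon": np.round(coords[:, 1], 6)}
    )
    if regions is not None:
        df["region"] = [regions[str(i)] for i in ids]
    df.to_csv(path, index=False)
    return path


def write_predictions(results: Sequence[PredictionResult], path) -> Path:
    path = Path(path)
    rows = []
    for r in results:
        row = {
            "id": r.individual_id,
            "lat": round(r.latitude, 6),
            "lon": round(r.longitude, 6),
            "best_population": r.best_match,
            "flags": ";".join(sorted(r.flags)),
        }
        for m, (name, d) in enumerate(r.nearest, start=1):
            row[f"pop_{m}"] = name
            row[f"gen_distance_{m}"] = round(d, 6)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_world(world: SyntheticWorld, outdir, *, seed_note: int | None = None) -> dict[str, Path]:
    """Write a synthetic world's artifacts (panel, Q, genotypes, freqs, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": write_panel(world.panel, outdir / "panel.csv"),
        "q_matrix": write_q_matrix(world.admixture, outdir / "Q.txt"),
        "genotypes": write_genotypes(world.individual_ids, world.genotypes, outdir / "genotypes.tsv"),
        "frequencies": write_frequencies(
            [f"C{k}" for k in range(world.ancestral_freqs.shape[0])],
            world.ancestral_freqs,
            outdir / "ancestral_freqs.csv",
        ),
        "truth": write_truth(
            world.individual_ids, world.coordinates, outdir / "truth.csv", regions=world.truth_regions()
        ),
    }
    meta = {"seed": world.config.seed if seed_note is None else seed_note, "config": vars(world.config)}
    for p in paths.values():
        write_sidecar(p, meta)
    return paths
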
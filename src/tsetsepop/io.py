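"""Readers and writers for the external formats the pipeline touches.

Genotypes travel as Genepop 4.x text, FSTAT ``.dat`` or a CSV mirror;
alignments as FASTA; wing landmarks as TPS (``LM=k`` blocks) or CSV; distance
matrices as PHYLIP square; trees as Newick.

Population/region/X-linkage metadata that the classic formats cannot carry is
kept in a JSON sidecar written next to the data file (``<path>.meta.json``).
When the sidecar is absent the readers fall back to conventions: individual
ids of the form ``pop|id``, region defaulting to the population name, and a
locus-name prefix ``X`` marking X-linkage (the convention the tsetse
microsatellite literature uses, e.g. ``XB104`` vs ``GPCAG``).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panels import (MISSING, DistanceMatrix, GenotypePanel, LandmarkPanel,
                     PanelValidationError, SequencePanel)

__all__ = [
    "ParseError",
    "read_genotypes", "write_genotypes",
    "read_alignment", "write_alignment",
    "read_landmarks", "write_landmarks",
    "read_distance_matrix", "write_distance_matrix",
    "read_newick", "write_newick",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# --------------------------------------------------------------------------
# sidecar metadata
# --------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def _write_sidecar(path, panel: GenotypePanel) -> None:
    meta = {
        "regions": panel.regions,
        "x_linked": [l for l, x in zip(panel.loci, panel.x_linked) if x],
        "sex": dict(zip(panel.ids, panel.sex.tolist())),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path) -> dict:
    p = _sidecar_path(path)
    if p.exists():
        return json.loads(p.read_text())
    return {}


def _x_flags(loci, meta) -> np.ndarray:
    # explicit sidecar wins; locus-name "X" prefix is the fallback
    if "x_linked" in meta:
        xset = set(meta["x_linked"])
        return np.array([l in xset for l in loci])
    return np.array([l.upper().startswith("X") for l in loci])


def _finalize_panel(ids, sexes, pops, loci, calls, meta) -> GenotypePanel:
    regions = meta.get("regions") or {p: p for p in set(pops)}
    for p in set(pops):
        regions.setdefault(p, p)
    x = _x_flags(loci, meta)
    sex_map = meta.get("sex", {})
    sexes = [sex_map.get(i, s) for i, s in zip(ids, sexes)]
    calls = np.asarray(calls, dtype=np.int64)
    # males written as identical homozygotes at X loci load as hemizygous
    sex_arr = np.asarray(sexes, dtype="U1")
    males = sex_arr == "M"
    for l in np.where(x)[0]:
        a, b = calls[males, l, 0], calls[males, l, 1]
        het = (a != MISSING) & (b != MISSING) & (a != b)
        if het.any():
            bad = np.where(males)[0][np.where(het)[0][0]]
            raise PanelValidationError(
                f"male heterozygote at X-linked locus {loci[l]}: "
                f"individual {ids[bad]}")
        calls[np.where(males)[0], l, 1] = MISSING
    return GenotypePanel(ids=list(ids), sex=sex_arr, populations=list(pops),
                         regions=regions, loci=list(loci), x_linked=x,
                         calls=calls)


def _split_id(raw: str, default_pop: str) -> tuple[str, str]:
    if "|" in raw:
        pop, ind = raw.split("|", 1)
        return pop.strip(), ind.strip()
    return default_pop, raw.strip()


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "genepop") -> GenotypePanel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_sidecar(path)
    if dialect == "genepop":
        return _read_genepop(path, meta)
    if dialect == "fstat":
        return _read_fstat(path, meta)
    if dialect == "csv":
        return _read_csv_genotypes(path, meta)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(panel: GenotypePanel, path, dialect: str = "genepop",
                    allele_digits: int | None = None) -> None:
    if panel.n_individuals == 0 or panel.n_loci == 0:
        raise ValueError("refusing to write an empty panel")
    for p in panel.population_names:
        if len(panel.individuals_in(p)) == 0:
            raise ValueError(f"empty population {p}")
    path = Path(path)
    if allele_digits is None:
        allele_digits = 3 if panel.calls.max() > 99 else 2
    if panel.calls.max() >= 10 ** allele_digits:
        raise ValueError(
            f"allele code {panel.calls.max()} not encodable "
            f"with {allele_digits} digits")
    if dialect == "genepop":
        _write_genepop(panel, path, allele_digits)
        _write_sidecar(path, panel)
    elif dialect == "fstat":
        _write_fstat(panel, path, allele_digits)   # writes its own sidecar
    elif dialect == "csv":
        _write_csv_genotypes(panel, path)
        _write_sidecar(path, panel)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_genepop(path: Path, meta: dict) -> GenotypePanel:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: too short for genepop")
    cursor = 1  # line 0 is the title
    loci: list[str] = []
    while cursor < len(lines) and lines[cursor].strip().lower() != "pop":
        chunk = lines[cursor].strip()
        if chunk:
            loci.extend(l.strip() for l in chunk.split(",") if l.strip())
        cursor += 1
    if not loci:
        raise ParseError(f"{path}: no locus names before first 'pop'")
    ids, sexes, pops, calls = [], [], [], []
    pop_counter = 0
    width = None
    for ln, line in enumerate(lines[cursor:], start=cursor + 1):
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            pop_counter += 1
            continue
        if "," not in line:
            raise ParseError(f"{path}:{ln}: expected 'id , genotypes'")
        raw_id, geno = line.split(",", 1)
        pop, ind = _split_id(raw_id, f"pop{pop_counter}")
        fields = geno.split()
        if len(fields) != len(loci):
            raise ParseError(
                f"{path}:{ln}: {len(fields)} genotypes for {len(loci)} loci")
        row = []
        for f, locus in zip(fields, loci):
            if not f.isdigit() or len(f) % 2:
                raise ParseError(f"{path}:{ln}: bad genotype {f!r} at {locus}")
            w = len(f) // 2
            if width is None:
                width = w
            elif w != width:
                raise ParseError(
                    f"{path}:{ln}: inconsistent allele-code width at {locus}")
            row.append((int(f[:w]), int(f[w:])))
        ids.append(ind)
        sexes.append("F")
        pops.append(pop)
        calls.append(row)
    if not ids:
        raise ParseError(f"{path}: no individuals")
    return _finalize_panel(ids, sexes, pops, loci, calls, meta)


def _write_genepop(panel: GenotypePanel, path: Path, digits: int) -> None:
    diploid = panel.diff_view()  # hemizygotes written as homozygotes
    out = ["tsetsepop genepop export"]
    out.extend(panel.loci)
    for pop in panel.population_names:
        out.append("pop")
        for i in panel.individuals_in(pop):
            genos = " ".join(
                f"{diploid.calls[i, l, 0]:0{digits}d}"
                f"{diploid.calls[i, l, 1]:0{digits}d}"
                for l in range(panel.n_loci))
            out.append(f"{pop}|{panel.ids[i]} , {genos}")
    path.write_text("\n".join(out) + "\n")


def _read_fstat(path: Path, meta: dict) -> GenotypePanel:
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    try:
        n_pop, n_loc, _max_all, digits = map(int, lines[0].split())
    except Exception as exc:
        raise ParseError(f"{path}:1: bad fstat header") from exc
    loci = [l.strip() for l in lines[1:1 + n_loc]]
    if len(loci) != n_loc:
        raise ParseError(f"{path}: expected {n_loc} locus names")
    pop_names = meta.get("population_order") \
        or [f"pop{i + 1}" for i in range(n_pop)]
    ids, sexes, pops, calls = [], [], [], []
    counters: dict[str, int] = {}
    id_order = meta.get("ids")
    for ln, line in enumerate(lines[1 + n_loc:], start=n_loc + 2):
        fields = line.split()
        if len(fields) != n_loc + 1:
            raise ParseError(f"{path}:{ln}: expected pop + {n_loc} genotypes")
        p = int(fields[0])
        if not 1 <= p <= n_pop:
            raise ParseError(f"{path}:{ln}: population index {p} out of range")
        pop = pop_names[p - 1]
        counters[pop] = counters.get(pop, 0) + 1
        row = []
        for f, locus in zip(fields[1:], loci):
            if not f.isdigit() or len(f) != 2 * digits:
                raise ParseError(f"{path}:{ln}: bad genotype {f!r} at {locus}")
            row.append((int(f[:digits]), int(f[digits:])))
        ids.append(f"{pop}_{counters[pop]}")
        sexes.append("F")
        pops.append(pop)
        calls.append(row)
    if id_order and len(id_order) == len(ids):
        ids = list(id_order)
    return _finalize_panel(ids, sexes, pops, loci, calls, meta)


def _write_fstat(panel: GenotypePanel, path: Path, digits: int) -> None:
    diploid = panel.diff_view()
    pop_names = panel.population_names
    out = [f"{len(pop_names)} {panel.n_loci} "
           f"{int(panel.calls.max())} {digits}"]
    out.extend(panel.loci)
    for pi, pop in enumerate(pop_names, start=1):
        for i in panel.individuals_in(pop):
            genos = " ".join(
                f"{diploid.calls[i, l, 0]:0{digits}d}"
                f"{diploid.calls[i, l, 1]:0{digits}d}"
                for l in range(panel.n_loci))
            out.append(f"{pi} {genos}")
    path.write_text("\n".join(out) + "\n")
    meta_path = _sidecar_path(path)
    # fstat sidecar additionally records population order and ids
    meta = {
        "regions": panel.regions,
        "x_linked": [l for l, x in zip(panel.loci, panel.x_linked) if x],
        "sex": dict(zip(panel.ids, panel.sex.tolist())),
        "population_order": pop_names,
        "ids": [panel.ids[i] for pop in pop_names
                for i in panel.individuals_in(pop)],
    }
    meta_path.write_text(json.dumps(meta, indent=1))


def _read_csv_genotypes(path: Path, meta: dict) -> GenotypePanel:
    import csv as _csv
    with open(path, newline="") as fh:
        rows = list(_csv.reader(fh))
    if not rows:
        raise ParseError(f"{path}: empty csv")
    header = rows[0]
    fixed = ["id", "sex", "population", "region"]
    if header[:4] != fixed:
        raise ParseError(f"{path}:1: header must start with {fixed}")
    loci = header[4:]
    ids, sexes, pops, calls = [], [], [], []
    regions: dict[str, str] = {}
    for ln, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != 4 + len(loci):
            raise ParseError(f"{path}:{ln}: wrong column count")
        ind, sex, pop, region = row[:4]
        regions[pop] = region
        gen = []
        for cell, locus in zip(row[4:], loci):
            cell = cell.strip()
            if cell in ("", "./.", "-"):
                gen.append((MISSING, MISSING))
            elif "/" in cell:
                a, b = cell.split("/")
                gen.append((int(a), int(b)))
            else:
                gen.append((int(cell), MISSING))
        ids.append(ind)
        sexes.append(sex or "F")
        pops.append(pop)
        calls.append(gen)
    meta = dict(meta)
    meta.setdefault("regions", regions)
    meta["sex"] = dict(zip(ids, sexes))
    return _finalize_panel(ids, sexes, pops, loci, calls, meta)


def _write_csv_genotypes(panel: GenotypePanel, path: Path) -> None:
    import csv as _csv
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["id", "sex", "population", "region"] + panel.loci)
        for i in range(panel.n_individuals):
            row = [panel.ids[i], panel.sex[i], panel.populations[i],
                   panel.regions[panel.populations[i]]]
            for l in range(panel.n_loci):
                a, b = panel.calls[i, l]
                if a == MISSING:
                    row.append("")
                elif b == MISSING:
                    row.append(str(a))
                else:
                    row.append(f"{a}/{b}")
            w.writerow(row)


# --------------------------------------------------------------------------
# alignments
# --------------------------------------------------------------------------

def read_alignment(path) -> SequencePanel:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    meta = _read_sidecar(path)
    ids, pops, seqs = [], [], []
    for rec in records:
        pop, ind = _split_id(rec.id, rec.id)
        ids.append(ind)
        pops.append(pop)
        seqs.append(str(rec.seq).upper())
    regions = meta.get("regions") or {p: p for p in set(pops)}
    for p in set(pops):
        regions.setdefault(p, p)
    try:
        return SequencePanel(ids=ids, populations=pops, regions=regions,
                             sequences=seqs)
    except PanelValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_alignment(panel: SequencePanel, path) -> None:
    records = [
        SeqRecord(Seq(s), id=f"{p}|{i}", description="")
        for i, p, s in zip(panel.ids, panel.populations, panel.sequences)]
    SeqIO.write(records, str(path), "fasta")
    _sidecar_path(path).write_text(json.dumps({"regions": panel.regions},
                                              indent=1))


# --------------------------------------------------------------------------
# landmarks
# --------------------------------------------------------------------------

_TPS_KEY = re.compile(r"^(LM|ID|IMAGE|SCALE)\s*=\s*(.*)$", re.I)


def read_landmarks(path, format: str = "tps") -> LandmarkPanel:
    path = Path(path)
    if format == "csv":
        return _read_landmarks_csv(path)
    if format != "tps":
        raise ValueError(f"unknown landmark format {format!r}")
    lines = path.read_text().splitlines()
    ids, groups, configs = [], [], []
    cur: list[list[float]] = []
    expect = None
    name = None
    ln_of_block = 0

    def close_block(ln):
        nonlocal cur, expect, name
        if expect is None:
            return
        if len(cur) != expect:
            raise ParseError(
                f"{path}:{ln_of_block}: block declares LM={expect} "
                f"but has {len(cur)} rows")
        raw = name if name is not None else f"config{len(ids) + 1}"
        grp, ind = _split_id(raw, raw)
        ids.append(ind)
        groups.append(grp)
        configs.append(cur)
        cur, expect, name = [], None, None

    for ln, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        m = _TPS_KEY.match(line)
        if m:
            key, val = m.group(1).upper(), m.group(2).strip()
            if key == "LM":
                close_block(ln)
                expect = int(val)
                ln_of_block = ln
            elif key == "ID":
                name = val
        else:
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 'x y'")
            cur.append([float(parts[0]), float(parts[1])])
    close_block(len(lines))
    if not configs:
        raise ParseError(f"{path}: no TPS blocks")
    ks = {len(c) for c in configs}
    if len(ks) != 1:
        raise ParseError(f"{path}: mixed landmark counts {sorted(ks)}")
    return LandmarkPanel(ids=ids, groups=groups,
                         configs=np.array(configs, dtype=float))


def write_landmarks(panel: LandmarkPanel, path, format: str = "tps") -> None:
    path = Path(path)
    if format == "csv":
        _write_landmarks_csv(panel, path)
        return
    out = []
    for i in range(panel.n):
        out.append(f"LM={panel.k}")
        for x, y in panel.configs[i]:
            out.append(f"{x:.10g} {y:.10g}")
        out.append(f"ID={panel.groups[i]}|{panel.ids[i]}")
    path.write_text("\n".join(out) + "\n")


def _read_landmarks_csv(path: Path) -> LandmarkPanel:
    import csv as _csv
    with open(path, newline="") as fh:
        rows = list(_csv.reader(fh))
    header = rows[0]
    if header[:2] != ["id", "group"]:
        raise ParseError(f"{path}:1: header must start with id,group")
    k2 = len(header) - 2
    if k2 % 2:
        raise ParseError(f"{path}:1: odd coordinate column count")
    ids, groups, configs = [], [], []
    for ln, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != 2 + k2:
            raise ParseError(f"{path}:{ln}: wrong column count")
        ids.append(row[0])
        groups.append(row[1])
        xy = np.array(row[2:], dtype=float).reshape(-1, 2)
        configs.append(xy)
    return LandmarkPanel(ids=ids, groups=groups, configs=np.array(configs))


def _write_landmarks_csv(panel: LandmarkPanel, path: Path) -> None:
    import csv as _csv
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        header = ["id", "group"]
        for j in range(panel.k):
            header += [f"x{j + 1}", f"y{j + 1}"]
        w.writerow(header)
        for i in range(panel.n):
            w.writerow([panel.ids[i], panel.groups[i]]
                       + [f"{v:.10g}" for v in panel.configs[i].ravel()])


# --------------------------------------------------------------------------
# distance matrices and trees
# --------------------------------------------------------------------------

def read_distance_matrix(path, statistic: str = "generic") -> DistanceMatrix:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    try:
        n = int(lines[0].split()[0])
    except Exception as exc:
        raise ParseError(f"{path}:1: expected taxon count") from exc
    labels, rows = [], []
    for ln, line in enumerate(lines[1:1 + n], start=2):
        parts = line.split()
        if len(parts) != n + 1:
            raise ParseError(f"{path}:{ln}: expected label + {n} values")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    if len(rows) != n:
        raise ParseError(f"{path}: expected {n} rows")
    return DistanceMatrix(labels, np.array(rows), statistic)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    out = [f"{len(dm.labels)}"]
    for lab, row in zip(dm.labels, dm.values):
        out.append(lab + "  " + "  ".join(f"{v:.8f}" for v in row))
    Path(path).write_text("\n".join(out) + "\n")


def read_newick(path):
    from skbio import TreeNode
    return TreeNode.read(str(path), format="newick")


def write_newick(tree, path) -> None:
    tree.write(str(path), format="newick")
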
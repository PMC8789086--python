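"""Readers and writers for genotype panels.

Supported formats:

* ``vcf`` — VCF 4.x text; phase read from ``|`` genotype separators
  (read via :mod:`cyvcf2`, written as plain text).
* ``plink_text`` — PLINK ``.ped`` / ``.map`` text pair (path names the
  common prefix). Unphased by convention.
* ``eigenstrat_text`` — EIGENSTRAT ``.geno`` / ``.snp`` / ``.ind`` text
  triple (path names the common prefix). geno digits count REF copies,
  so ALT dosage = 2 - digit; 9 is missing.

Sample metadata (population, major group, coordinates) travels in a
separate delimited table; see :func:`read_metadata` / :func:`attach_metadata`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PanelError


class ParseError(ValueError):
    """A file failed to parse under the named format."""


_FORMATS = ("vcf", "plink_text", "eigenstrat_text")


def read_panel(path: str, format: str = "vcf") -> GenotypePanel:
    """Read a genotype panel from ``path`` in the given format."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_text":
        return _read_plink(path)
    return _read_eigenstrat(path)


def write_panel(panel: GenotypePanel, path: str, format: str = "vcf") -> None:
    """Write ``panel`` to ``path``; lossless round-trip with :func:`read_panel`."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    if format == "vcf":
        _write_vcf(panel, path)
    elif format == "plink_text":
        _write_plink(panel, path)
    else:
        _write_eigenstrat(panel, path)


# ---------------------------------------------------------------- VCF


def _read_vcf(path: str) -> GenotypePanel:
    from cyvcf2 import VCF

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise ParseError(f"{path}: not parseable as VCF: {exc}") from exc
    samples = list(vcf.samples)
    n = len(samples)
    geno_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    records = []
    all_phased = True
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ParseError(
                f"{path}: record {i + 1} ({var.CHROM}:{var.POS}) is not biallelic"
            )
        gts = var.genotypes  # list of [allele0, allele1, phased]
        row = np.empty(n, dtype=np.int8)
        hrow = np.empty(2 * n, dtype=np.int8)
        for j, gt in enumerate(gts):
            if len(gt) != 3:
                raise ParseError(
                    f"{path}: record {i + 1}, sample {samples[j]}: ploidy != 2"
                )
            a, b, phased = gt
            if a < 0 or b < 0:
                row[j] = MISSING
                hrow[2 * j] = 0
                hrow[2 * j + 1] = 0
                continue
            row[j] = a + b
            hrow[2 * j] = a
            hrow[2 * j + 1] = b
            if not phased and a != b:
                all_phased = False
        geno_rows.append(row)
        hap_rows.append(hrow)
        records.append(
            (var.CHROM, var.POS, _cm_from_info(var), var.REF, var.ALT[0], var.ID or ".")
        )
    snp_table = pd.DataFrame(records, columns=["chrom", "pos", "cm", "ref", "alt", "id"])
    genotypes = (
        np.array(geno_rows, dtype=np.int8).T
        if geno_rows
        else np.empty((n, 0), dtype=np.int8)
    )
    haplotypes = None
    if all_phased and hap_rows:
        haplotypes = np.array(hap_rows, dtype=np.int8).T
    sample_table = pd.DataFrame({"id": samples})
    return GenotypePanel(genotypes, snp_table, sample_table, haplotypes)


def _cm_from_info(var) -> float:
    cm = var.INFO.get("CM")
    return float(cm) if cm is not None else float("nan")


def _write_vcf(panel: GenotypePanel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.snp_table["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(panel.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        phased = panel.phased
        sep = "|" if phased else "/"
        for k, snp in enumerate(panel.snp_table.itertuples(index=False)):
            info = "." if np.isnan(snp.cm) else f"CM={snp.cm:.6g}"
            fields = [
                str(snp.chrom),
                str(snp.pos),
                str(snp.id),
                str(snp.ref),
                str(snp.alt),
                ".",
                "PASS",
                info,
                "GT",
            ]
            for i in range(panel.n_samples):
                g = panel.genotypes[i, k]
                if g == MISSING:
                    fields.append(f".{sep}.")
                elif phased:
                    a = panel.haplotypes[2 * i, k]
                    b = panel.haplotypes[2 * i + 1, k]
                    fields.append(f"{a}|{b}")
                else:
                    fields.append("0/1" if g == 1 else ("1/1" if g == 2 else "0/0"))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------- PLINK text


def _read_plink(prefix: str) -> GenotypePanel:
    map_path, ped_path = prefix + ".map", prefix + ".ped"
    for p in (map_path, ped_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    records = []
    known_alleles: list[tuple[str, str] | None] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) not in (4, 6):
                raise ParseError(f"{map_path}:{lineno}: expected 4 or 6 fields")
            chrom, snp_id, cm, pos = parts[:4]
            records.append((chrom, int(pos), float(cm), snp_id))
            # extended dialect: ref/alt columns resolve the allele-coding
            # ambiguity of bare .ped sites that are monomorphic
            known_alleles.append((parts[4], parts[5]) if len(parts) == 6 else None)
    n_snps = len(records)
    sample_ids, rows = [], []
    alleles: list[dict[str, int]] = [dict() for _ in range(n_snps)]
    raw: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(parts)}"
                )
            sample_ids.append(parts[1])
            pairs = [
                (parts[6 + 2 * k], parts[7 + 2 * k]) for k in range(n_snps)
            ]
            raw.append(pairs)
            for k, (a, b) in enumerate(pairs):
                for al in (a, b):
                    if al != "0":
                        alleles[k].setdefault(al, len(alleles[k]))
    ref_alt = []
    for k, seen in enumerate(alleles):
        obs = sorted(seen)
        if len(obs) > 2:
            raise ParseError(f"{ped_path}: SNP {records[k][3]} has >2 alleles")
        if known_alleles[k] is not None:
            ref, alt = known_alleles[k]
            extra = [a for a in obs if a not in (ref, alt)]
            if extra:
                raise ParseError(
                    f"{ped_path}: SNP {records[k][3]} has alleles {extra} "
                    "not in the map's ref/alt columns"
                )
        else:
            # bare 4-column map: lexicographic REF < ALT among observed
            ref = obs[0] if obs else "A"
            alt = obs[1] if len(obs) > 1 else _other_allele(ref)
        ref_alt.append((ref, alt))
    for pairs in raw:
        row = np.empty(n_snps, dtype=np.int8)
        for k, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                row[k] = MISSING
            else:
                row[k] = (a == ref_alt[k][1]) + (b == ref_alt[k][1])
        rows.append(row)
    snp_table = pd.DataFrame(
        [
            (chrom, pos, cm, ra[0], ra[1], sid)
            for (chrom, pos, cm, sid), ra in zip(records, ref_alt)
        ],
        columns=["chrom", "pos", "cm", "ref", "alt", "id"],
    )
    genotypes = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, n_snps), dtype=np.int8)
    )
    return GenotypePanel(genotypes, snp_table, pd.DataFrame({"id": sample_ids}))


def _other_allele(ref: str) -> str:
    return "T" if ref != "T" else "A"


def _write_plink(panel: GenotypePanel, prefix: str) -> None:
    with open(prefix + ".map", "w") as fh:
        for snp in panel.snp_table.itertuples(index=False):
            cm = 0.0 if np.isnan(snp.cm) else snp.cm
            fh.write(
                f"{snp.chrom}\t{snp.id}\t{cm:.6g}\t{snp.pos}\t{snp.ref}\t{snp.alt}\n"
            )
    ref = panel.snp_table["ref"].to_numpy()
    alt = panel.snp_table["alt"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for k in range(panel.n_snps):
                g = panel.genotypes[i, k]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [ref[k], ref[k]]
                elif g == 2:
                    fields += [alt[k], alt[k]]
                else:
                    fields += [ref[k], alt[k]]
            fh.write(" ".join(str(f) for f in fields) + "\n")


# ---------------------------------------------------------------- EIGENSTRAT


def _read_eigenstrat(prefix: str) -> GenotypePanel:
    geno_p, snp_p, ind_p = prefix + ".geno", prefix + ".snp", prefix + ".ind"
    for p in (geno_p, snp_p, ind_p):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    records = []
    with open(snp_p) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) not in (4, 6):
                raise ParseError(f"{snp_p}:{lineno}: expected 4 or 6 fields")
            sid, chrom, cm_morgans, pos = parts[:4]
            ref, alt = (parts[4], parts[5]) if len(parts) == 6 else ("A", "T")
            # EIGENSTRAT stores genetic position in morgans
            records.append((chrom, int(pos), 100.0 * float(cm_morgans), ref, alt, sid))
    ids, pops = [], []
    with open(ind_p) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{ind_p}:{lineno}: expected 3 fields")
            ids.append(parts[0])
            pops.append(parts[2])
    rows = []
    with open(geno_p) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if len(line) != len(ids):
                raise ParseError(
                    f"{geno_p}:{lineno}: {len(line)} genotypes for {len(ids)} samples"
                )
            try:
                digits = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            except Exception as exc:
                raise ParseError(f"{geno_p}:{lineno}: non-digit genotype") from exc
            if not np.isin(digits, [0, 1, 2, 9]).all():
                raise ParseError(f"{geno_p}:{lineno}: genotype digit not in 0/1/2/9")
            row = np.where(digits == 9, MISSING, 2 - digits).astype(np.int8)
            rows.append(row)
    if len(rows) != len(records):
        raise ParseError(f"{geno_p}: {len(rows)} rows for {len(records)} SNPs")
    snp_table = pd.DataFrame(records, columns=["chrom", "pos", "cm", "ref", "alt", "id"])
    genotypes = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(ids), 0), dtype=np.int8)
    )
    sample_table = pd.DataFrame({"id": ids, "population": pops})
    return GenotypePanel(genotypes, snp_table, sample_table)


def _write_eigenstrat(panel: GenotypePanel, prefix: str) -> None:
    with open(prefix + ".snp", "w") as fh:
        for snp in panel.snp_table.itertuples(index=False):
            cm = 0.0 if np.isnan(snp.cm) else snp.cm
            fh.write(
                f"{snp.id}\t{snp.chrom}\t{cm / 100.0:.8g}\t{snp.pos}"
                f"\t{snp.ref}\t{snp.alt}\n"
            )
    pops = (
        panel.sample_table["population"]
        if "population" in panel.sample_table
        else ["???"] * panel.n_samples
    )
    with open(prefix + ".ind", "w") as fh:
        for sid, pop in zip(panel.sample_ids, pops):
            fh.write(f"{sid}\tU\t{pop}\n")
    with open(prefix + ".geno", "w") as fh:
        for k in range(panel.n_snps):
            col = panel.genotypes[:, k]
            digits = np.where(col == MISSING, 9, 2 - col)
            fh.write("".join(str(int(d)) for d in digits) + "\n")


# ---------------------------------------------------------------- metadata


def read_metadata(path: str, sep: str = "\t") -> pd.DataFrame:
    """Read a sample metadata table (id, population, major_group, lat, lon)."""
    meta = pd.read_csv(path, sep=sep)
    if "id" not in meta.columns:
        raise ParseError(f"{path}: metadata table must have an 'id' column")
    return meta


def attach_metadata(panel: GenotypePanel, meta: pd.DataFrame) -> GenotypePanel:
    """Left-join metadata columns onto the panel's sample table by id."""
    merged = panel.sample_table[["id"]].merge(meta, on="id", how="left")
    if len(merged) != panel.n_samples:
        raise PanelError("metadata join changed the number of samples")
    return GenotypePanel(
        panel.genotypes, panel.snp_table, merged, panel.haplotypes
    )
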
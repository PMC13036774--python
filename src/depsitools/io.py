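"""Readers and writers for the pipeline's file formats.

MGF is the canonical spectrum format (mzML can be converted through a
thin adapter, see :func:`read_mzml`).  Domain annotations travel as TSV
derived from GenBank-style feature tables.  Trees are Newick, networks
GraphML plus TSV tables.  All nucleotide coordinates in files are
1-based inclusive; in-memory coordinates are 0-based half-open.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .bgc import DistanceTree, DomainAnnotation, DotPlotMatrix, NrpsBgc, PiProfile
from .fragments import AnnotationResult, Spectrum
from .network import MolecularFamily, NetworkEdge

__all__ = [
    "DataError",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "read_domain_table",
    "write_domain_table",
    "read_fasta",
    "write_fasta",
    "write_newick",
    "write_network",
    "write_pi_profile",
    "write_dotplot",
    "write_annotation",
    "write_event_log",
    "write_provenance",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# spectra


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF file into Spectrum objects.

    PEPMASS, CHARGE ("2+" -> 2) and TITLE are parsed; a block without
    PEPMASS raises :class:`DataError` naming the spectrum index/title.
    """
    from pyteomics import mgf

    spectra = []
    try:
        with mgf.MGF(str(path)) as reader:
            for k, entry in enumerate(reader):
                params = entry.get("params", {})
                title = params.get("title", f"spectrum_{k}")
                if "pepmass" not in params or params["pepmass"][0] is None:
                    raise DataError(f"spectrum {k} ({title!r}) is missing PEPMASS")
                pepmass = float(params["pepmass"][0])
                charge = int(params["charge"][0]) if params.get("charge") else 1
                peaks = list(
                    zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())
                )
                spectra.append(Spectrum(peaks, pepmass, charge, str(title)))
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"failed to parse MGF {path}: {exc}") from exc
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    """Write spectra to MGF (peak values kept to 6 decimals)."""
    from pyteomics import mgf

    entries = []
    for k, s in enumerate(spectra):
        entries.append(
            {
                "m/z array": np.round(np.array(s.mz, dtype=float), 6),
                "intensity array": np.round(np.array(s.intensities, dtype=float), 6),
                "params": {
                    "title": s.id or f"spectrum_{k}",
                    "pepmass": round(s.precursor_mz, 6),
                    "charge": s.precursor_charge,
                },
            }
        )
    mgf.write(entries, output=str(path), file_mode="w")


def read_mzml(path) -> list[Spectrum]:
    """Thin adapter: MS2 spectra from an mzML file as Spectrum objects."""
    from pyteomics import mzml

    spectra = []
    with mzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            try:
                precursor = entry["precursorList"]["precursor"][0][
                    "selectedIonList"
                ]["selectedIon"][0]
                pepmass = float(precursor["selected ion m/z"])
                charge = int(precursor.get("charge state", 1))
            except (KeyError, IndexError) as exc:
                raise DataError(f"mzML spectrum without precursor info: {exc}") from exc
            peaks = list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            spectra.append(Spectrum(peaks, pepmass, charge, entry.get("id", "")))
    return spectra


# ---------------------------------------------------------------------------
# domain tables

_DOMAIN_COLUMNS = [
    "bgc_id",
    "gene_id",
    "domain_kind",
    "start",
    "end",
    "strand",
    "aa_sequence",
    "substrate_prediction",
]


def read_domain_table(path) -> list[NrpsBgc]:
    """Read a domain-annotation TSV into NrpsBgc objects.

    Expected columns: bgc_id, gene_id, domain_kind, start, end (1-based
    inclusive), strand, aa_sequence, substrate_prediction.  Domains are
    grouped per cluster, ordered by coordinates; module inference
    applies downstream (module count = A-domain count).
    """
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        if reader.fieldnames is None:
            raise DataError(f"domain table {path} is empty")
        missing = set(_DOMAIN_COLUMNS[:5]) - set(reader.fieldnames)
        if missing:
            raise DataError(f"domain table {path} lacks columns: {sorted(missing)}")
        rows = list(reader)
    if not rows:
        raise DataError(f"domain table {path} contains no records")
    by_bgc: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in rows:
        bgc_id = row["bgc_id"]
        if bgc_id not in by_bgc:
            order.append(bgc_id)
        by_bgc.setdefault(bgc_id, []).append(row)
    bgcs = []
    for bgc_id in order:
        domains = []
        genes: list[str] = []
        for row in by_bgc[bgc_id]:
            if row["gene_id"] not in genes:
                genes.append(row["gene_id"])
            try:
                domains.append(
                    DomainAnnotation(
                        kind=row["domain_kind"],
                        gene_id=row["gene_id"],
                        start=int(row["start"]) - 1,  # 1-based inclusive -> 0-based
                        end=int(row["end"]),
                        strand=row.get("strand") or "+",
                        aa_sequence=row.get("aa_sequence") or None,
                        substrate_prediction=row.get("substrate_prediction") or None,
                    )
                )
            except ValueError as exc:
                raise DataError(f"bad domain row in {bgc_id}: {exc}") from exc
        domains.sort(key=lambda d: (genes.index(d.gene_id), d.start))
        try:
            bgcs.append(NrpsBgc(bgc_id, genes, domains))
        except ValueError as exc:
            raise DataError(f"inconsistent annotations for {bgc_id}: {exc}") from exc
    return bgcs


def write_domain_table(bgcs: list[NrpsBgc], path) -> None:
    """Write NrpsBgc domain annotations as TSV (1-based inclusive)."""
    with open(path, "w", newline="") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_DOMAIN_COLUMNS)
        for bgc in bgcs:
            for d in bgc.domains:
                writer.writerow(
                    [
                        bgc.id,
                        d.gene_id,
                        d.kind,
                        d.start + 1,
                        d.end,
                        d.strand,
                        d.aa_sequence or "",
                        d.substrate_prediction or "",
                    ]
                )


# ---------------------------------------------------------------------------
# sequences and trees


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_newick(tree: DistanceTree, path) -> None:
    text = tree.newick()
    if tree.support:
        pass  # support values are reported separately; topology stays plain
    Path(path).write_text(text + ("\n" if not text.endswith("\n") else ""))


# ---------------------------------------------------------------------------
# networks and profiles


def write_network(
    edges: list[NetworkEdge],
    families: list[MolecularFamily],
    spectra: list[Spectrum],
    out_prefix,
) -> dict[str, Path]:
    """Write edge TSV, node TSV and GraphML for a molecular network."""
    import networkx as nx

    out_prefix = Path(out_prefix)
    family_of = {}
    for fam in families:
        for member in fam.members:
            family_of[member] = fam.label
    edge_path = out_prefix.with_suffix(".edges.tsv")
    with open(edge_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["node_a", "node_b", "cosine", "matched_peaks", "delta_mz"])
        for e in edges:
            writer.writerow(
                [e.node_a, e.node_b, f"{e.cosine:.4f}", e.matched_peaks, f"{e.delta_mz:.4f}"]
            )
    node_path = out_prefix.with_suffix(".nodes.tsv")
    with open(node_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "precursor_mz", "precursor_charge", "family"])
        for k, s in enumerate(spectra):
            sid = s.id or f"spectrum_{k}"
            writer.writerow([sid, f"{s.precursor_mz:.4f}", s.precursor_charge, family_of.get(sid, "")])
    g = nx.Graph()
    for k, s in enumerate(spectra):
        sid = s.id or f"spectrum_{k}"
        g.add_node(sid, precursor_mz=s.precursor_mz, family=int(family_of.get(sid, -1)))
    for e in edges:
        g.add_edge(e.node_a, e.node_b, cosine=e.cosine, matched_peaks=e.matched_peaks)
    graphml_path = out_prefix.with_suffix(".graphml")
    nx.write_graphml(g, graphml_path)
    return {"edges": edge_path, "nodes": node_path, "graphml": graphml_path}


def write_pi_profile(profile: PiProfile, path) -> None:
    """TSV of window midpoints (1-based alignment coordinates) and pi."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# window width {profile.width} nt, step {profile.step} nt; midpoints 1-based\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["midpoint", "pi"])
        for mid, pi in zip(profile.midpoints, profile.values):
            writer.writerow([f"{mid + 1:.1f}", f"{pi:.6f}"])


def write_dotplot(dp: DotPlotMatrix, path) -> None:
    """Sparse TSV of word matches (1-based start coordinates)."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# word size {dp.word} nt; coordinates 1-based\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["i", "j"])
        for i, j in dp.matches:
            writer.writerow([i + 1, j + 1])


def write_annotation(result: AnnotationResult, path) -> None:
    """TSV of matched fragment ions."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["ion", "series", "index", "losses", "charge", "mz", "peak_index", "ppm_error"])
        for ion, peak_idx, err in result.matches:
            writer.writerow(
                [
                    ion.label(),
                    ion.series,
                    ion.index,
                    ";".join(sorted(ion.losses)),
                    ion.charge,
                    f"{ion.mz:.6f}",
                    peak_idx,
                    f"{err:.3f}",
                ]
            )
        fh.write(f"# ladder_coverage\t{result.ladder_coverage:.4f}\n")


def write_event_log(log: dict, path) -> None:
    Path(path).write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")


def write_provenance(path, subcommand: str, params: dict, seed: int | None) -> None:
    """Machine-readable record of a run: parameters, versions, seed."""
    from importlib.metadata import version

    try:
        pkg_version = version("depsitools")
    except Exception:
        pkg_version = "unknown"
    record = {
        "tool": "depsitools",
        "version": pkg_version,
        "subcommand": subcommand,
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "seed": seed,
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
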
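"""Genome annotations to ordered Pfam-domain tracks.

Detection operates on a genome represented as the ordered chain of Pfam
domains along its genes. This module builds that chain: parse per-domain
tabular output of a profile-HMM search (HMMER3 ``domtblout``), keep
significant hits, resolve overlapping hits on each gene greedily by bitscore,
and sort the survivors by gene rank then envelope start. It can also drive
the external tools (prodigal for ORF calling, hmmsearch for the domain scan)
when they are on PATH; their absence is a capability error, not a library
failure.

Coordinates are 1-based inclusive residue positions (the HMMER convention);
any exported interval tracks use 0-based half-open and say so in headers.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

DEFAULT_EVALUE_CUTOFF = 1e-5


class CapabilityError(RuntimeError):
    """A required external executable is not available."""


class DomtblFormatError(ValueError):
    pass


@dataclass
class DomainHit:
    gene_id: str
    gene_order: int
    pfam_acc: str
    env_start: int  # 1-based inclusive
    env_end: int    # 1-based inclusive
    bitscore: float
    evalue: float

    def overlaps(self, other: "DomainHit") -> bool:
        return self.env_start <= other.env_end and other.env_start <= self.env_end


@dataclass
class GenomeDomainTrack:
    """Ordered Pfam-domain chain of one genome, with optional BGC labels."""

    genome_id: str
    domains: list[DomainHit]
    labels: list[int] | None = None       # 1 = domain inside a BGC
    starts: list[int] | None = None       # 1 = first domain of a BGC

    def __post_init__(self) -> None:
        for name in ("labels", "starts"):
            vec = getattr(self, name)
            if vec is not None and len(vec) != len(self.domains):
                raise ValueError(f"{name} length {len(vec)} != #domains {len(self.domains)}")

    def __len__(self) -> int:
        return len(self.domains)

    @property
    def pfam_accessions(self) -> list[str]:
        return [h.pfam_acc for h in self.domains]

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            cols = "genome_id\tgene_order\tgene_id\tpfam_acc\tenv_start\tenv_end\tbitscore\tevalue"
            labelled = self.labels is not None
            if labelled:
                cols += "\tlabel\tstart_label"
            fh.write("#" + cols + "\n")
            for i, h in enumerate(self.domains):
                row = (f"{self.genome_id}\t{h.gene_order}\t{h.gene_id}\t{h.pfam_acc}"
                       f"\t{h.env_start}\t{h.env_end}\t{h.bitscore:g}\t{h.evalue:g}")
                if labelled:
                    starts = self.starts or [0] * len(self.domains)
                    row += f"\t{self.labels[i]}\t{starts[i]}"
                fh.write(row + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GenomeDomainTrack":
        domains: list[DomainHit] = []
        labels: list[int] = []
        starts: list[int] = []
        genome_id = ""
        labelled = False
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                genome_id = parts[0]
                domains.append(DomainHit(
                    gene_id=parts[2], gene_order=int(parts[1]), pfam_acc=parts[3],
                    env_start=int(parts[4]), env_end=int(parts[5]),
                    bitscore=float(parts[6]), evalue=float(parts[7])))
                if len(parts) >= 10:
                    labelled = True
                    labels.append(int(parts[8]))
                    starts.append(int(parts[9]))
        return cls(genome_id, domains,
                   labels if labelled else None, starts if labelled else None)


# ---------------------------------------------------------------------------
# domtblout parsing
# ---------------------------------------------------------------------------

def strip_version(acc: str) -> str:
    """``PF00001.21`` -> ``PF00001``."""
    head, _, tail = acc.partition(".")
    return head if tail.isdigit() else acc


def parse_domtbl(path: str | Path, evalue_cutoff: float | None = DEFAULT_EVALUE_CUTOFF
                 ) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output (``--domtblout``).

    Column layout (whitespace-delimited): target name, target acc, tlen,
    query name, query acc, qlen, full-seq E-value/score/bias, domain index,
    #domains, c-Evalue, i-Evalue, domain score/bias, hmm from/to, ali
    from/to, env from/to, acc, description. The query is the Pfam model;
    the target is the protein (gene). ``gene_order`` is the order of first
    appearance of each gene in the file. Hits with independent E-value above
    ``evalue_cutoff`` are dropped (pass ``None`` to keep everything).
    """
    hits: list[DomainHit] = []
    gene_rank: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 21:
                raise DomtblFormatError(
                    f"{path}:{lineno}: expected >=21 whitespace-delimited columns")
            gene_id = parts[0]
            query_acc = parts[4] if parts[4] != "-" else parts[3]
            try:
                i_evalue = float(parts[12])
                bitscore = float(parts[13])
                env_start = int(parts[19])
                env_end = int(parts[20])
            except ValueError as exc:
                raise DomtblFormatError(f"{path}:{lineno}: non-numeric field: {exc}") from None
            if evalue_cutoff is not None and i_evalue > evalue_cutoff:
                continue
            if gene_id not in gene_rank:
                gene_rank[gene_id] = len(gene_rank)
            hits.append(DomainHit(
                gene_id=gene_id, gene_order=gene_rank[gene_id],
                pfam_acc=strip_version(query_acc),
                env_start=env_start, env_end=env_end,
                bitscore=bitscore, evalue=i_evalue))
    return hits


def write_domtbl(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits back out in a minimal valid domtblout layout (fixture writer)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# minimal domtblout written by bgclm\n")
        for h in hits:
            fields = [
                h.gene_id, "-", "500", h.pfam_acc, h.pfam_acc + ".1", "200",
                f"{h.evalue:g}", f"{h.bitscore:g}", "0.0", "1", "1",
                f"{h.evalue:g}", f"{h.evalue:g}", f"{h.bitscore:g}", "0.0",
                "1", "200", str(h.env_start), str(h.env_end),
                str(h.env_start), str(h.env_end), "0.90", "-",
            ]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Overlap resolution and ordering
# ---------------------------------------------------------------------------

def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy per-gene non-overlap filter.

    Hits are taken in descending bitscore (ties: smaller env_start, then
    lexicographic Pfam accession); a hit is kept iff it shares no residue
    with any already-kept hit. All hits must be on the same gene. This is a
    documented, injectable stand-in for an external resolver.
    """
    genes = {h.gene_id for h in hits}
    if len(genes) > 1:
        raise ValueError(f"resolve_overlaps expects hits on one gene, got {sorted(genes)}")
    ranked = sorted(hits, key=lambda h: (-h.bitscore, h.env_start, h.pfam_acc))
    kept: list[DomainHit] = []
    for h in ranked:
        if not any(h.overlaps(k) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.env_start)
    return kept


def order_track(hits: Sequence[DomainHit], genome_id: str) -> GenomeDomainTrack:
    """Stable sort by (gene rank along the genome, envelope start)."""
    ordered = sorted(hits, key=lambda h: (h.gene_order, h.env_start))
    return GenomeDomainTrack(genome_id, list(ordered))


def assign_gene_order(hits: Sequence[DomainHit], gene_ids_in_order: Sequence[str]) -> None:
    """Re-rank hits by the gene order of the ORF caller's output (in place).

    hmmsearch reports targets per query sorted by score, so file order is not
    genome order; the protein FASTA from the ORF caller is.
    """
    rank = {g: i for i, g in enumerate(gene_ids_in_order)}
    for h in hits:
        if h.gene_id not in rank:
            raise ValueError(f"gene {h.gene_id!r} absent from ORF output")
        h.gene_order = rank[h.gene_id]


def hits_to_track(hits: Sequence[DomainHit], genome_id: str,
                  resolver: Callable[[Sequence[DomainHit]], list[DomainHit]] = resolve_overlaps
                  ) -> GenomeDomainTrack:
    """Per-gene overlap resolution followed by genome-wide ordering."""
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    resolved = [h for gene_hits in by_gene.values() for h in resolver(gene_hits)]
    return order_track(resolved, genome_id)


# ---------------------------------------------------------------------------
# External-tool orchestration (optional capability)
# ---------------------------------------------------------------------------

@dataclass
class ToolConfig:
    hmm_path: str | Path | None = None          # profile-HMM database for hmmsearch
    prodigal_exe: str = "prodigal"
    hmmsearch_exe: str = "hmmsearch"
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    prodigal_args: tuple[str, ...] = ("-p", "meta")


def _run(cmd: list[str]) -> None:
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"{cmd[0]} failed (exit {proc.returncode}): {proc.stderr.strip()}")


def annotate_genome(fasta_path: str | Path, tool_config: ToolConfig,
                    genome_id: str | None = None,
                    domtbl_path: str | Path | None = None,
                    proteins_path: str | Path | None = None) -> GenomeDomainTrack:
    """Genome FASTA -> ordered Pfam-domain track.

    Pipeline: ORF prediction (prodigal) -> per-gene profile-HMM search
    (hmmsearch) -> parse -> per-gene overlap resolution -> ordering. A
    precomputed ``domtbl_path`` bypasses both tools; a precomputed
    ``proteins_path`` bypasses ORF calling only.
    """
    genome_id = genome_id or Path(fasta_path).stem
    if domtbl_path is not None:
        hits = parse_domtbl(domtbl_path, evalue_cutoff=tool_config.evalue_cutoff)
        return hits_to_track(hits, genome_id)

    if tool_config.hmm_path is None:
        raise ValueError("tool_config.hmm_path is required to run hmmsearch")
    if shutil.which(tool_config.hmmsearch_exe) is None:
        raise CapabilityError(f"{tool_config.hmmsearch_exe} not found on PATH")

    with tempfile.TemporaryDirectory(prefix="bgclm_annot_") as tmp:
        tmp_dir = Path(tmp)
        if proteins_path is None:
            if shutil.which(tool_config.prodigal_exe) is None:
                raise CapabilityError(f"{tool_config.prodigal_exe} not found on PATH")
            # empty FASTA: prodigal has nothing to call; short-circuit to empty track
            if Path(fasta_path).stat().st_size == 0:
                return GenomeDomainTrack(genome_id, [])
            proteins_path = tmp_dir / "proteins.faa"
            _run([tool_config.prodigal_exe, "-i", str(fasta_path),
                  "-a", str(proteins_path), "-o", str(tmp_dir / "genes.gbk"),
                  *tool_config.prodigal_args])
        if Path(proteins_path).stat().st_size == 0:
            return GenomeDomainTrack(genome_id, [])
        domtbl = tmp_dir / "hits.domtbl"
        _run([tool_config.hmmsearch_exe, "--domtblout", str(domtbl), "--noali",
              str(tool_config.hmm_path), str(proteins_path)])
        hits = parse_domtbl(domtbl, evalue_cutoff=tool_config.evalue_cutoff)
        from Bio import SeqIO
        gene_ids = [rec.id for rec in SeqIO.parse(str(proteins_path), "fasta")]
        assign_gene_order(hits, gene_ids)
    return hits_to_track(hits, genome_id)
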
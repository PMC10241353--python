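"""From profile-HMM search output to an ordered genome domain track.

Parses HMMER3 per-domain tabular output (domtblout), keeps significant
hits, greedily resolves overlapping hits on each gene by bitscore, and
orders the survivors by gene rank then envelope start — the representation
the detection machinery consumes. Uses a small in-memory fixture; point
``parse_domtbl`` at real hmmsearch output for real genomes.
"""

import tempfile
from pathlib import Path

import bgclm as bg

hits = [
    bg.DomainHit("gene2", 1, "PF00501", 10, 450, 320.0, 1e-90),   # AMP-binding
    bg.DomainHit("gene1", 0, "PF00109", 5, 230, 210.0, 1e-60),    # ketoacyl-synt
    bg.DomainHit("gene1", 0, "PF02801", 240, 380, 180.0, 1e-50),  # KAsynt_C
    bg.DomainHit("gene1", 0, "PF00108", 200, 300, 40.0, 1e-8),    # overlaps both
    bg.DomainHit("gene3", 2, "PF08659", 1, 180, 150.0, 1e-40),    # KR domain
]

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "hits.domtbl"
    bg.write_domtbl(hits, path)
    parsed = bg.parse_domtbl(path)           # E-value filter, version stripping
    print(f"parsed {len(parsed)} significant hits")

track = bg.hits_to_track(parsed, genome_id="demo_genome")
print("ordered domain chain:", " -> ".join(track.pfam_accessions))
print("note: PF00108 (bitscore 40) was dropped — it overlaps higher-scoring")
print("hits on gene1; survivors are sorted by (gene order, envelope start).")
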
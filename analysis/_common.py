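"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from paraconv.experiments import flagship_config
from paraconv.seq_io import read_alignment, read_regions, write_alignment, write_regions
from paraconv.simulate import simulate_history

RESULTS = Path(__file__).resolve().parent.parent / "results"
FLAGSHIP = RESULTS / "flagship"
SEED = 2017


def ensure_flagship():
    """Simulate the flagship five-species scenario once; reuse thereafter."""
    FLAGSHIP.mkdir(parents=True, exist_ok=True)
    fasta = FLAGSHIP / "alignment.fasta"
    cfg, regions = flagship_config(SEED)
    if not fasta.exists():
        aln, truth = simulate_history(cfg)
        write_alignment(aln, fasta)
        truth.to_json(FLAGSHIP / "truth.json")
        write_regions(regions, FLAGSHIP / "regions.tsv")
    return cfg, read_alignment(fasta), read_regions(FLAGSHIP / "regions.tsv")
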
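"""End-to-end convenience pipelines over the library modules."""

from __future__ import annotations

from . import markerdesign as md
from . import repeatmask, simulate, synteny


def core_genome_from_truth(truth: simulate.PanGenomeTruth):
    """Chain the truth alignments of a simulated pan-genome into blocks,
    build the coverage profile and extract the core."""
    blocks = {}
    for name, _seq in truth.assemblies:
        chains = synteny.chain_anchors(truth.truth_alignments[name])
        blocks[name] = synteny.select_one_to_one(chains, name)
    profile, core = synteny.coverage_and_core(
        blocks, {truth.reference_name: truth.ref_len}
    )
    return blocks, profile, core


def design_default_panel(seed: int):
    """Full default marker-design run on a fixed-seed synthetic pan-genome.

    Simulates the default pan-genome (2 Mb, 5 assemblies, 30% dispensable)
    and diversity panel, masks repeats, builds the core, and designs
    spaced amplicon markers with default parameters.  Returns
    ``(truth, designs)``.
    """
    truth = simulate.simulate_pangenome(seed)
    _blocks, profile, core = core_genome_from_truth(truth)
    panel_vcf = simulate.simulate_panel_variants(truth, seed=seed)
    seqs = {truth.reference_name: truth.reference}
    table = repeatmask.count_kmers(seqs)
    masked = repeatmask.mask_repeats(seqs, table)
    stats = md.region_stats(core, panel_vcf, profile=profile)
    candidates = md.filter_candidates(stats)
    selected = md.select_spaced_markers(
        candidates, all_regions=stats, seed=seed,
        ref_lengths={truth.reference_name: truth.ref_len},
    )
    designs = md.design_amplicons(selected, masked, panel_vcf)
    return truth, designs
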
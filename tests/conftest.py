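"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import pytest

from coremark import hapcall, simulate


@pytest.fixture(scope="session")
def pangenome():
    """Small pan-genome: 400 kb reference, 3 assemblies, 20% dispensable."""
    return simulate.simulate_pangenome(
        11, ref_len=400_000, n_assemblies=3, dispensable_frac=0.2, repeat_frac=0.05
    )


@pytest.fixture(scope="session")
def family_with_reads(tmp_path_factory):
    """F1 family (12 markers, 30 progeny) with simulated amplicon reads."""
    panel, parents = simulate.simulate_cross_inputs(n_markers=12, seed=5)
    fam = simulate.simulate_family(parents, "F1", n_progeny=30, recomb_rate=3.0, seed=5)
    outdir = tmp_path_factory.mktemp("reads")
    paths = simulate.simulate_amplicon_reads(
        panel, fam, outdir,
        depth_log10_mean=1.7, depth_log10_sd=0.3,
        sub_error=0.005, homopolymer_indel=0.002, seed=5,
    )
    return panel, parents, fam, paths


@pytest.fixture(scope="session")
def called_family(family_with_reads):
    """Genotype matrix called end-to-end from the shared family reads."""
    panel, parents, fam, paths = family_with_reads
    ped = hapcall.Pedigree.from_family(fam)
    hc = hapcall.demultiplex_reads(paths, panel)
    collapsed = hapcall.collapse_haplotypes(hc, ped)
    matrix = hapcall.call_genotypes(collapsed, ped.samples)
    return panel, fam, ped, hc, collapsed, matrix


def truth_insert(panel, marker_id: str, allele: str) -> str:
    """Primer-trimmed amplicon insert of a truth allele."""
    m = panel.get(marker_id)
    return allele[len(m.fwd_primer) : -len(m.rev_primer)]
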
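"""Allele mixing in homodimers: cis versus posttranslational assembly.

A heterozygous locus expresses wild-type and mutant subunits in equal
amounts.  If dimers assemble only after translation, subunit pairing is
random and half of all complexes are wild-type:mutant hybrids, which a
dominant-negative mutant can poison; only a quarter remain pure wild-type.
If assembly happens cotranslationally in cis, every complex is allele-pure
and half of them are fully functional.
"""

from assembly_buffer import simulate_assembly

N = 1_000_000

for cis in (0.0, 0.5, 1.0):
    out = simulate_assembly(N, cis_fraction=cis, seed=1)
    print(
        f"cis fraction {cis:.1f}: "
        f"pure wild-type {100 * out.pure_wt_fraction:5.2f}%  "
        f"mixed {100 * out.mixed_fraction:5.2f}%  "
        f"pure mutant {100 * out.pure_mut_fraction:5.2f}%"
    )

print(
    "\nThe pure wild-type share climbs from ~25% (random assembly) to ~50% "
    "(strict cis assembly):\nallele-specific assembly buffers the "
    "dominant-negative effect by keeping mutants out of half the pool."
)
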
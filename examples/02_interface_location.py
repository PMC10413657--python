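"""Interface area profiles and where the interface sits along the chain.

Subunits that expose their interface early (N-terminally) can start
assembling while still on the ribosome; C-terminally shifted interfaces
only become available late in translation, disfavouring cotranslational
assembly.  We build two synthetic homodimers — one with an N-terminal and
one with a C-terminal interface — and compare their location metrics.
"""

from assembly_buffer import (
    gen_homodimer_structure,
    half_area_position,
    interface_profile,
    interface_shift,
    relative_interface_location,
)

for label, center in [("N-terminal interface", 0.1), ("C-terminal interface", 0.9)]:
    dimer = gen_homodimer_structure(100, center, 0.2, seed=1)
    profile = interface_profile(dimer, "A")
    ril = relative_interface_location(profile)
    half = half_area_position(profile)
    print(f"{label}:")
    print(f"  total interface area       {profile.total_area:7.1f} A^2")
    print(f"  relative interface location {ril:6.3f}  (0 = N terminus, 1 = C terminus)")
    print(f"  half of the area exposed at {100 * half:5.1f}% of translation")

shift = interface_shift(observed=0.55, basemean=0.49)
print(
    f"\nA subunit at relative location 0.55 in a symmetry group whose mean "
    f"is 0.49 is shifted {shift:+.0f}% of its length toward the C terminus — "
    f"the signature of complexes prone to dominant-negative mutations."
)
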
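"""Tally signs of infection from PCR and serology screening.

An animal counts once if it is PCR-positive in either screened tissue or
antibody-positive — overlaps are subtracted, never double-counted.
"""

from pvgc import ScreeningCounts, infection_sign_union, prevalence_percent

counts = ScreeningCounts(
    pcr_pos_tissue1=23,        # chest-cavity fluid PCR positives
    pcr_pos_tissue2=41,        # kidney PCR positives
    pcr_pos_both_tissues=2,    # positive in both tissues
    sero_pos=17,               # VP1-antibody positives
    sero_pos_and_pcr_pos=6,    # seropositive AND PCR-positive
    total_animals=172,
)

union = infection_sign_union(counts)
pct = prevalence_percent(union, counts.total_animals)
print(f"animals with any sign of infection: {union} of "
      f"{counts.total_animals} ({pct}%)")
print(
    "\n(23 + 41 - 2) PCR-positive animals plus (17 - 6) additional"
    "\nseropositives = 73; each animal is counted exactly once."
)
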
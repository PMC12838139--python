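"""Generate a synthetic marker family and verify the planted ground truth.

The generator plants a known set of species-diagnostic columns inside the
hypervariable interval; the site profiler must recover every planted column
(plus any diagnostic sites arising from the random background divergence).
"""

from specprime import diagnostic_sites, site_profile
from specprime.compstats import records_to_trivial_alignment
from specprime.fixtures import SyntheticFamilySpec, generate_family

spec = SyntheticFamilySpec(seed=42)
records, truth = generate_family(spec)

print(f"{spec.n_species} species, {spec.n_sites} nt coding sequences, "
      f"hotspot {spec.hotspot[0]}-{spec.hotspot[1]}")
profile = site_profile(records_to_trivial_alignment(records))
for species in sorted(truth):
    found = diagnostic_sites(profile, species)
    planted = truth[species]
    recovered = set(planted) <= set(found)
    print(f"{species}: {len(planted)} planted diagnostic columns, "
          f"{len(found)} total diagnostic columns found, "
          f"planted recovered: {recovered}")
print("\nPlanted columns are always a subset of the called diagnostic sites; "
      "extra\nsites arise naturally from the calibrated background divergence.")
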
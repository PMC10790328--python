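"""From a raw native-MS profile to bound-state mole fractions.

Simulates the spectrum of a 58 kDa transporter equilibrated with 20 uM PI
(charge states 13+..19+, up to four lipid adducts), then runs the full
analysis chain: centroiding, charge-series deconvolution to the zero-charge
mass, lipid-adduct assignment against the built-in lipid table, and
intensity-based mole fractions.
"""

from msbind.chem import get_lipid
from msbind.nativems import assign_lipid_adducts, deconvolve_mass, mole_fractions, pick_peaks
from msbind.simulate import SPECTRUM_PRESETS, gen_spectrum

profile, inventory = gen_spectrum(SPECTRUM_PRESETS["fl-pi-20uM"], seed=7)
print(f"profile: {len(profile)} samples; inventory: {len(inventory)} true peaks")

centroids = pick_peaks(profile, min_spacing=6.0)
series = deconvolve_mass(centroids, z_range=(12, 22))
base = min(series, key=lambda s: s.mass)  # lowest mass = the apo series
print(f"apo mass {base.mass:.1f} Da over charges {base.charges}")

adducts = assign_lipid_adducts(centroids, base, [get_lipid("PI(18:1/18:1)")])
fractions = mole_fractions(adducts).iloc[0]
for k, value in enumerate(fractions):
    print(f"x{k} = {value:.3f}")
# x0 is the apo fraction; x1..x4 are the one- to four-lipid-bound species.
# At 20 uM PI the bound species outweigh apo and four events are detectable.
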
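"""Within-species scaling: estimate b and read the N:C trend as b − 1.

Simulates one within-species dataset of 1000 cells with a planted
size-scaling exponent b = 0.58 (the steep end of what bacteria and yeasts
show), fits the allometry nucleus = a·cell^b on log10–log10 axes with all
three supported line-fitting methods, and rearranges to the N:C slope.
"""

from karyoscale import (
    classify_isometry,
    fit_allometry,
    fold_change_per_decade,
    nc_ratio_slope,
    simulate_within_species,
)

cells = simulate_within_species(b=0.58, log10_a=-0.6, n=1000, seed=42)

for method in ("ols", "major_axis", "quantile"):
    fit = fit_allometry(
        cells["cell_volume_um3"], cells["nucleus_volume_um3"], method=method
    )
    print(
        f"{method:>10}: b = {fit.b:.3f} [{fit.b_ci[0]:.3f}, {fit.b_ci[1]:.3f}]"
        f"  -> {classify_isometry(fit)}"
    )

fit = fit_allometry(cells["cell_volume_um3"], cells["nucleus_volume_um3"])
slope, (lo, hi) = nc_ratio_slope(fit)
print(f"\nN:C ratio slope (b-1): {slope:.3f} [{lo:.3f}, {hi:.3f}]")
print(f"10-fold larger cells have {fold_change_per_decade(fit):.2f}x larger nuclei")
# b < 1 with a CI excluding 1 (equivalently, b-1 excluding 0): larger cells
# have relatively smaller nuclei — the N:C ratio falls with cell size.
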
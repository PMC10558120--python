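"""Shade-tolerance trait metrics and the ground-light interception proxy.

Computes the community-weighted mean (CWM) and functional dispersion
(FDis) of shade tolerance from a mixture census, and the mean daytime
light intensity at 20 cm from four simulated sensors.
"""

from standweave import community_traits, light_interception_proxy, synthetic

pool = synthetic.default_species_pool()
design = synthetic.generate_design(pool, seed=1)
plot = next(p for p in design.plots if p.richness == 4)

census = synthetic.simulate_growth(
    synthetic.layout_plot(plot, seed=5, pool=pool), pool, seed=6
)
traits = {s: sp.shade_tolerance for s, sp in pool.items()}
ct = community_traits(census, traits, plot_id=plot.plot_id)
print(f"plot {plot.plot_id} ({'+'.join(plot.composition)})")
print(f"CWM shade tolerance: {ct.cwm:.3f}  (abundance-weighted community mean)")
print(f"FDis:                {ct.fd:.3f}  (dispersion around the weighted centroid)")

series = synthetic.simulate_light(plot, census, pool, seed=7)
summary = light_interception_proxy(series)
print(f"mean daytime light:  {summary.mean_intensity:.1f} (arbitrary units)")
print("per sensor:          "
      + ", ".join(f"{k}={v:.1f}" for k, v in summary.per_sensor.items()))
# high FDis = mixture of tolerant (low-canopy) and intolerant (tall)
# species — the trait contrast that drives vertical stratification; low
# light means strong interception by the canopy above the sensors
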
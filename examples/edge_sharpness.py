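"""Edge sharpness: fit a Gaussian CDF to an edge-spread function.

Generates a noisy synthetic edge profile (the forward model), conditions it
(Savitzky-Golay + cubic spline), fits the CDF model and reports σ, FWHM and
NRMSE.  The FWHM is the sharpness figure of merit: lower = sharper.
"""
import bonetomo as bt

x, y = bt.generate_edge_profile(
    mu=0.0, sigma=2.0, levels=(9000, 32000), n_points=200,
    noise_sigma=0.05 * 23000, seed=7,
)
profile = bt.LineProfile(x, y, units="px")
conditioned = bt.condition_profile(profile, savgol_span=9, upsample_factor=4)
fit = bt.fit_edge(conditioned)

print(f"true sigma      : 2.000 px")
print(f"fitted sigma    : {fit.sigma:.3f} px")
print(f"FWHM            : {fit.fwhm:.3f} px  (= 2.3548 * sigma)")
print(f"NRMSE           : {fit.nrmse:.4f}")
print(f"edge position mu: {fit.mu:.3f} px")
# The fitted sigma recovers the generator's blur within a few percent even
# at 5% contrast noise; NRMSE ~ 0.01 signals a clean sigmoid fit.
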
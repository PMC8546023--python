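"""The exponent algebra: (alpha, H) <-> (beta, z) and the phase diagram.

Forward-maps a few model points to their observable exponents, then inverts
the experimentally measured spectral exponents of Nav1.6 sodium channels.
"""

from subfbm import classify_regime, exponents_forward, exponents_invert

print("model point        regime   beta     z      MSD-lag  MSD-aging")
for alpha, hurst in [(0.7, 0.5), (0.4, 0.3), (0.4, 0.7), (0.8, 0.75),
                     (1.0, 0.5)]:
    es = exponents_forward(alpha, hurst)
    print(f"a={alpha:.1f}, H={hurst:<5.2f}  {es.regime:>6}  {es.beta:6.2f}"
          f"  {es.z:+6.2f}  {es.msd_lag_exp:7.2f}  {es.msd_aging_exp:+8.2f}")
print("z < 0: fluctuations decay with observation time (aging);")
print("z > 0: they grow (rejuvenation, regime III, 2*alpha*H > 1).")

print()
print("Inverting the measured ion-channel exponents:")
psd = exponents_invert(beta=1.75, z=-0.50, branch="I")
print(f"  spectra beta=1.75, z=-0.50  ->  alpha={psd.alpha:.2f}, "
      f"H={psd.hurst:.2f}")
msd = exponents_invert(branch="MSD", msd_lag_exp=0.81, msd_aging_exp=-0.46)
print(f"  TA-MSD lag=0.81, aging=-0.46 ->  alpha={msd.alpha:.2f}, "
      f"H={msd.hurst:.2f}")
print("Two independent observables give the same (alpha, H): the")
print("subordinated-fBM picture is self-consistent for these channels.")
print(f"regime at the recovered point: {classify_regime(0.5, 0.25)}")
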
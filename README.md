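# shadowtrack

Shadowing-filter reconstruction of animal-movement trajectories: recover
the closest **Newtonian** trajectory — positions, velocities and
accelerations — from noisy, gappy, irregularly sampled GPS position fixes.

Miniature GPS loggers record position only, at finite precision and with
frequent dropouts, yet movement analyses (behavioural segmentation,
energetics, collective dynamics) need the full dynamical state including
acceleration. Direct differentiation of positions amplifies fix noise into
unphysical spikes. `shadowtrack` instead fits the whole series at once:
assuming piecewise-constant acceleration a_i on each interval
[t_i, t_{i+1}) of length T_i, it finds the trajectory minimizing

    J = ½ Σ_i σ_i⁻² (P_i − p_i)²  +  η Σ_i T_i a_i²

subject to p_{i+1} = p_i + v_i T_i + ½ a_i T_i² and v_{i+1} = v_i + a_i T_i,
solved by SVD least squares (with an independent KKT solver for
verification). The smoothing weight η can be taken from the device noise
variance β via η ≈ 0.046 β³ + 0.054 (valid at high sampling rates) or
optimized by a seeded replicate-sweep simulation. A windowing test reports
the minimum number of fixes needed for a reliable estimate, and a
sliding-average + finite-difference baseline is included for comparison.
The package targets movement ecologists and anyone reconstructing phase
space from position-only tracking data.

## Worked example

```python
import numpy as np
from shadowtrack import (SyntheticSpec, simulate_true_track, observe,
                         filter_track, FilterConfig, eta_from_noise,
                         rms_error, segment_flight)

spec = SyntheticSpec(seed=42)          # 30 s maneuvering flight, 0.2 s fixes
truth = simulate_true_track(spec)
obs = observe(truth, spec)             # 0.4 m^2 noise, 36% dropouts
eta = eta_from_noise(0.4)
traj = filter_track(obs.drop_invalid(), FilterConfig(eta=eta))

kept = np.isin(truth.times, obs.drop_invalid().times)
print(f"eta from device noise:       {eta:.6f}")
print(f"kept fixes:                  {obs.drop_invalid().n_samples} of {obs.n_samples}")
print(f"raw observation RMS error:   {rms_error(obs.drop_invalid().values, truth.positions[kept]):.3f} m")
print(f"filtered position RMS error: {rms_error(traj.positions, truth.positions[kept]):.3f} m")
print(f"flight segments (>4 m/s):    {segment_flight(traj.speeds)}")
```

Output:

```
eta from device noise:       0.056944
kept fixes:                  97 of 151
raw observation RMS error:   0.892 m
filtered position RMS error: 0.433 m
flight segments (>4 m/s):    [(4, 97)]
```

The noise-matched η halves the position error relative to the raw fixes
even after discarding the 36% of samples the device failed to log, and the
reconstructed velocity magnitude cleanly segments the flight phase
(samples 4–97 exceed the 4 m/s threshold). `traj.velocities` and
`traj.accelerations` hold the rest of the phase space; no numerical
differentiation is ever applied to noisy positions.

The same operations are available as scikit-learn style estimators
(`ShadowingFilter(eta=...).fit(X, times=t)` with `positions_`,
`velocities_`, `accelerations_` attributes) and from the command line:

```
shadowtrack simulate --output obs.csv --truth truth.csv --seed 42
shadowtrack track --input obs.csv --beta 0.4 --output filtered.csv
shadowtrack sweep --input obs.csv --grid default --output sweep.csv
shadowtrack window-test --input obs.csv --eta 0.05 --lengths 10,20,40 --output wt.csv
shadowtrack baseline --input obs.csv --window 5 --output base.csv
```

Track CSVs use the header `t,x[,y[,z]][,signal]` (seconds, meters;
signal 1 = device-logged fix, 0 = interpolated).

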
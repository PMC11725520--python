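# Default parameter sets for the three human circadian pacemaker models.
#
# Values are transcribed from the original model publications:
#   forger99    - Forger, Jewett & Kronauer (1999), the "simpler" van der Pol
#                 pacemaker with Process L photoreceptor dynamics.
#   jewett99    - Jewett, Forger & Kronauer (1999), the revised higher-order
#                 van der Pol limit-cycle oscillator.
#   hannay19_sp - Hannay, Booth & Forger (2019), single-population macroscopic
#                 (Kuramoto-reduction) model with synchrony amplitude R.
#
# Units: tau in hours; alpha0 and beta in 1/min (the photoreceptor ODE carries
# the 60 min/h conversion); I0 in lux; all coupling constants dimensionless
# except psi_cbt (radians).
forger99:
  tau: 24.2
  photoreceptor:
    alpha0: 0.05
    beta: 0.0075
    p: 0.5
    I0: 9500.0
    G: 33.75
  coupling:
    mu: 0.23
    k: 0.55
    period_correction: 0.99669

jewett99:
  tau: 24.2
  photoreceptor:
    alpha0: 0.16
    beta: 0.013
    p: 0.6
    I0: 9500.0
    G: 19.875
  coupling:
    mu: 0.13
    k: 0.55
    q: 0.3333333333333333
    period_correction: 0.99729

hannay19_sp:
  tau: 23.84
  photoreceptor:
    alpha0: 0.05
    beta: 0.0075
    p: 1.5
    I0: 9325.0
    G: 33.75
  coupling:
    gamma: 0.024
    K: 0.06358
    beta1: -0.09318
    A1: 0.3855
    A2: 0.1977
    betaL1: -0.0026
    betaL2: -0.957756
    sigma: 0.0400692
    psi_cbt: 3.141592653589793
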
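"""Published comparison tables used as reference inputs.

Table 1 lists the axial velocity u(y) and Table 2 the stream function
psi(y) at x = 1 for zeta=0.01, alpha=0.2, eps=0.15, delta=0.01, F=0.1
(Table 2's caption omits zeta; 0.01 is assumed), each as a perturbation
column, a numerical column and their difference, on y = 0, 0.1, ..., 1.1.
"""

import numpy as np

TABLE_PARAMS = {"zeta": 0.01, "alpha": 0.2, "eps": 0.15, "delta": 0.01, "F": 0.1}
TABLE_X = 1.0

Y_GRID = np.round(np.arange(0.0, 1.2, 0.1), 10)

TABLE1_U_PERTURB = np.array([
    0.564385, 0.552597, 0.517232, 0.458275, 0.375705, 0.269491,
    0.13959, -0.0140506, -0.191489, -0.392793, -0.618037, -0.867319,
])
TABLE1_U_NUMERICAL = np.array([
    0.564638, 0.552843, 0.517455, 0.458461, 0.375841, 0.269569,
    0.139607, -0.0140875, -0.191567, -0.392894, -0.618137, -0.867374,
])
TABLE1_DIFFERENCE = np.array([
    -2.53724e-4, -2.4605e-4, -2.23174e-4, -1.8578e-4, -1.35904e-4,
    -7.76974e-5, -1.75488e-5, 3.68592e-5, 7.83305e-5, 1.01432e-4,
    1.00026e-4, 5.51864e-5,
])

TABLE2_PSI_PERTURB = np.array([
    0.0, 0.0560456, 0.109734, 0.158706, 0.200601, 0.233058,
    0.25371, 0.260185, 0.250107, 0.221092, 0.17075, 0.0966832,
])
TABLE2_PSI_NUMERICAL = np.array([
    0.0, 0.0560623, 0.109766, 0.15875, 0.200655, 0.233115,
    0.253765, 0.260233, 0.250144, 0.221116, 0.170762, 0.0966849,
])
TABLE2_DIFFERENCE = np.array([
    0.0, -1.67013e-5, -3.20222e-5, -4.45712e-5, -5.31095e-5,
    -5.67039e-5, -5.49514e-5, -4.81658e-5, -3.74213e-5, -2.44263e-5,
    -1.14196e-5, -1.73212e-6,
])
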
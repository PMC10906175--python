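{
  "name": "laa-tissue-ogden3",
  "description": "Third-order nearly incompressible Ogden coefficients for left atrial appendage tissue, fitted to biaxial test data; D1 derived from mu_i and Poisson's ratio 0.495, D2 = D3 = 0.",
  "units": {"mu": "MPa", "alpha": "-", "D": "1/MPa", "density": "kg/m^3"},
  "order": 3,
  "mu": [-0.337741884, 0.217246844, 0.122674830],
  "alpha": [2.00175982, 4.001398310, -1.998378080],
  "D": [9.205880052, 0.0, 0.0],
  "poisson": 0.495,
  "density": 1120.0
}
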
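{
 "params": {
  "dP2": 0.1,
  "dNm": 2.0,
  "dL3": 0.3,
  "dL3pb": 0.02,
  "dMbm": 0.1,
  "dMpb": 0.6,
  "dMAC": 0.02,
  "aHSC": 0.95,
  "mrHSC": 0.7205764611689354,
  "sHSC": 0.4,
  "dHSC": 0.05,
  "fN": 0.55,
  "fL": 0.25,
  "fM": 0.2,
  "kHSC": 190.0,
  "kBM": 240826.0909784643,
  "aN2": 0.7,
  "mrN2": 2.0,
  "sN2": 0.5,
  "kN": 51938.74417534403,
  "mbN": 2.154027597837025,
  "mgN": 3.75,
  "dmN": 1.0770137989185125,
  "kNmp": 16000.0,
  "rN": 0.5,
  "kNbm": 16000.0,
  "aL2": 0.7,
  "mrL2": 1.0,
  "sL2": 0.2,
  "kL": 25353.450093510197,
  "mbL": 0.021577694548571082,
  "rL": 0.5,
  "kLt": 4000.0,
  "aM2": 0.65,
  "mrM2": 1.5,
  "sM2": 0.3,
  "kM": 14217.436004566303,
  "mbM": 0.6168806808712147,
  "mgM": 2.0,
  "dmM": 1.028134468118691,
  "kMmp": 1600.0,
  "rM": 0.5,
  "kMbm": 1600.0,
  "actM": 0.2,
  "kA": 1000.0,
  "mrMAC": 0.4,
  "clA": 0.05,
  "clAM": 1.0,
  "kMAC": 30.0,
  "chKill": 1.2,
  "chElim": 1.0,
  "capacity": 300000.0,
  "cancer": {
   "dMc": 0.1,
   "aMc2": 0.65,
   "mrMc2": 1.5,
   "mbMc": 0.6168806808712147,
   "sMc": 0.3
  }
 },
 "equilibrium": [
  9.999999999079897,
  16840.16412076875,
  7999.999999999149,
  3999.9999999995744,
  3999.9999999996367,
  709.2483990922454,
  2000.0000010706947,
  2000.0000009139744,
  399.0420339335391,
  800.0000006275068,
  400.00000032943245,
  400.00000027908095,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0
 ],
 "criteria": {
  "equilibrium_residual": 3.839318196696695e-09,
  "c1": true,
  "c2": true,
  "c3": true,
  "c4": true,
  "c5": true,
  "c6": true,
  "c7": true,
  "accepted": true,
  "stem_equilibrium": 9.999999999079897
 }
}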
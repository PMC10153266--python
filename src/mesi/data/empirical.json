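{
 "meta": {
  "peak_rho_step": 0.005,
  "peak_poly_degree": 10,
  "b0_log10_gamma_range": [
   -2.0,
   1.0
  ],
  "binf_log10_gamma_range": [
   -2.0,
   2.0
  ],
  "boundary_rhos": [
   0.5,
   0.6,
   0.7,
   0.7999999999999999,
   0.8999999999999999,
   0.9999999999999999
  ]
 },
 "peak_poly": {
  "0": [
   -0.5574098906782644,
   0.3215669638271129,
   -0.01805295885250682,
   0.0011398937908990968,
   -0.06128719350229549,
   0.10750046045885168,
   -0.13795374615611747,
   0.07009703210865774,
   0.005598212398328779,
   -0.009901962512879454
  ],
  "1": [
   -0.3322016573251976,
   0.20145906879431794,
   -0.017012861377117747,
   -0.0025188367750207203,
   -0.052759432988991134,
   0.12195821474256942,
   -0.21673520681478883,
   0.22198359343367283,
   -0.11274321368568858,
   0.022470351444196613
  ]
 },
 "boundary": {
  "0": {
   "b0": [
    1.0,
    -0.12761075412540504,
    2.3893143967426047,
    -1.8584299353812277,
    2.110483582476966
   ],
   "binf": [
    -0.0018315709837785753,
    0.9549230990210751,
    0.5036737406610947,
    0.36529812763815744,
    0.04667191623495466
   ]
  },
  "1": {
   "b0": [
    0.5,
    1.1705898639700578,
    1.0008769578408974,
    -0.1007738290791861,
    0.16609337534350552
   ],
   "binf": [
    0.4902478612600967,
    0.1501571429431085,
    1.2636014473208925,
    0.2367335580672783,
    0.1636849848280638
   ]
  }
 }
}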
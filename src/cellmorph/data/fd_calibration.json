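{
 "grid_size": 1024,
 "n_theta": 4096,
 "sigma": 0.12,
 "k_min": 2,
 "k_max": 512,
 "seeds_per_beta": 16,
 "beta": [
  6.0,
  5.0,
  4.5,
  4.0,
  3.6,
  3.8,
  3.4,
  3.2,
  3.0,
  2.8,
  2.6,
  2.4,
  2.2,
  2.0,
  1.8,
  1.6,
  1.4,
  1.2,
  1.0,
  0.8
 ],
 "fd": [
  1.0129088654066716,
  1.0133098760222046,
  1.0136923562559779,
  1.0161956560649104,
  1.0174187400987968,
  1.0174187400987968,
  1.0198892380753202,
  1.0249839462794164,
  1.0392990803145314,
  1.051662279303324,
  1.0738796208641044,
  1.1049349486138555,
  1.1561482889663384,
  1.2074830759968236,
  1.257472376428045,
  1.3136250126925855,
  1.3727631541637406,
  1.4174948853978084,
  1.4652275101851662,
  1.50335285804911
 ],
 "fd_sd": [
  0.004977071082983489,
  0.004662870950097712,
  0.005937325951925109,
  0.007827168609486838,
  0.010278884666480465,
  0.008129504856491245,
  0.009364089368140066,
  0.016047081522219255,
  0.016579943065947237,
  0.02069608490522659,
  0.031121655455518045,
  0.03671747239558343,
  0.034805538415205464,
  0.03489470601384019,
  0.025310872131913957,
  0.029951401182110336,
  0.018241863762294926,
  0.017290245458576877,
  0.012379617040184745,
  0.010185400895907274
 ]
}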
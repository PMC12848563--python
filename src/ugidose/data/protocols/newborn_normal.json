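{
 "age_class": "newborn",
 "diagnosis": "normal",
 "pulse_rate_hz": 7.5,
 "fields": [
  {
   "id": "1N",
   "projection": "left-lateral",
   "fluoro_seconds": 5.0,
   "spot_film": false,
   "box": {
    "z_lo": [
     "lungs",
     "lo",
     -1.0
    ],
    "z_hi": [
     "tongue",
     "hi",
     1.0
    ],
    "width_fraction": 0.95
   }
  },
  {
   "id": "2N",
   "projection": "left-lateral",
   "fluoro_seconds": 5.0,
   "spot_film": false,
   "box": {
    "z_lo": [
     "oesophagus",
     "lo",
     -0.5
    ],
    "z_hi": [
     "tongue",
     "hi",
     0.5
    ],
    "width_fraction": 0.45
   }
  },
  {
   "id": "3N",
   "projection": "left-lateral",
   "fluoro_seconds": 10.0,
   "spot_film": false,
   "box": {
    "z_lo": [
     "oesophagus",
     "lo",
     -0.5
    ],
    "z_hi": [
     "tongue",
     "hi",
     0.5
    ],
    "width_fraction": 0.45
   },
   "contrast": {
    "tongue": [
     [
      "ez_paque",
      0.3
     ],
     [
      "__base__",
      0.7
     ]
    ],
    "oesophagus": [
     [
      "ez_paque",
      1.0
     ]
    ]
   }
  },
  {
   "id": "4N",
   "projection": "left-lateral",
   "fluoro_seconds": 10.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "stomach_contents",
     "mid",
     0.0
    ],
    "z_hi": [
     "tongue",
     "hi",
     0.5
    ],
    "width_fraction": 0.5
   },
   "contrast": {
    "tongue": [
     [
      "ez_paque",
      0.1
     ],
     [
      "__base__",
      0.9
     ]
    ],
    "oesophagus": [
     [
      "ez_paque",
      1.0
     ]
    ],
    "stomach_contents": [
     [
      "ez_paque",
      0.1
     ],
     [
      "__base__",
      0.9
     ]
    ]
   }
  },
  {
   "id": "5N",
   "projection": "PA",
   "fluoro_seconds": 10.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "stomach_wall",
     "lo",
     -1.0
    ],
    "z_hi": [
     "stomach_wall",
     "hi",
     3.0
    ],
    "width_fraction": 0.65
   },
   "contrast": {
    "oesophagus": [
     [
      "ez_paque",
      1.0
     ]
    ],
    "stomach_contents": [
     [
      "ez_paque",
      0.4
     ],
     [
      "__base__",
      0.6
     ]
    ]
   }
  },
  {
   "id": "6N",
   "projection": "right-lateral",
   "fluoro_seconds": 10.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "si_wall",
     "lo",
     -0.5
    ],
    "z_hi": [
     "stomach_wall",
     "hi",
     0.5
    ],
    "width_fraction": 0.7
   },
   "contrast": {
    "stomach_contents": [
     [
      "ez_paque",
      1.0
     ]
    ],
    "si_contents": [
     [
      "ez_paque",
      0.1
     ],
     [
      "__base__",
      0.9
     ]
    ]
   }
  },
  {
   "id": "7N",
   "projection": "right-lateral",
   "fluoro_seconds": 10.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "si_wall",
     "lo",
     -0.5
    ],
    "z_hi": [
     "stomach_wall",
     "hi",
     0.5
    ],
    "width_fraction": 0.7
   },
   "contrast": {
    "stomach_contents": [
     [
      "ez_paque",
      0.9
     ],
     [
      "__base__",
      0.1
     ]
    ],
    "si_contents": [
     [
      "ez_paque",
      0.2
     ],
     [
      "__base__",
      0.8
     ]
    ]
   }
  },
  {
   "id": "8N",
   "projection": "PA",
   "fluoro_seconds": 10.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "si_wall",
     "lo",
     -0.5
    ],
    "z_hi": [
     "stomach_wall",
     "hi",
     0.5
    ],
    "width_fraction": 0.75
   },
   "contrast": {
    "stomach_contents": [
     [
      "ez_paque",
      0.9
     ],
     [
      "__base__",
      0.1
     ]
    ],
    "si_contents": [
     [
      "ez_paque",
      0.2
     ],
     [
      "__base__",
      0.8
     ]
    ]
   }
  },
  {
   "id": "9N",
   "projection": "LPO15",
   "fluoro_seconds": 5.0,
   "spot_film": true,
   "box": {
    "z_lo": [
     "si_wall",
     "lo",
     -0.5
    ],
    "z_hi": [
     "stomach_wall",
     "mid",
     0.0
    ],
    "width_fraction": 0.6
   },
   "contrast": {
    "stomach_contents": [
     [
      "ez_paque",
      0.9
     ],
     [
      "__base__",
      0.1
     ]
    ],
    "si_contents": [
     [
      "ez_paque",
      0.2
     ],
     [
      "__base__",
      0.8
     ]
    ]
   }
  }
 ]
}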
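{
 "24-2": {
  "spacing_deg": 6,
  "active": [
   [
    1,
    3
   ],
   [
    1,
    4
   ],
   [
    1,
    5
   ],
   [
    1,
    6
   ],
   [
    2,
    2
   ],
   [
    2,
    3
   ],
   [
    2,
    4
   ],
   [
    2,
    5
   ],
   [
    2,
    6
   ],
   [
    2,
    7
   ],
   [
    3,
    1
   ],
   [
    3,
    2
   ],
   [
    3,
    3
   ],
   [
    3,
    4
   ],
   [
    3,
    5
   ],
   [
    3,
    6
   ],
   [
    3,
    7
   ],
   [
    3,
    8
   ],
   [
    4,
    0
   ],
   [
    4,
    1
   ],
   [
    4,
    2
   ],
   [
    4,
    3
   ],
   [
    4,
    4
   ],
   [
    4,
    5
   ],
   [
    4,
    6
   ],
   [
    4,
    8
   ],
   [
    5,
    0
   ],
   [
    5,
    1
   ],
   [
    5,
    2
   ],
   [
    5,
    3
   ],
   [
    5,
    4
   ],
   [
    5,
    5
   ],
   [
    5,
    6
   ],
   [
    5,
    8
   ],
   [
    6,
    1
   ],
   [
    6,
    2
   ],
   [
    6,
    3
   ],
   [
    6,
    4
   ],
   [
    6,
    5
   ],
   [
    6,
    6
   ],
   [
    6,
    7
   ],
   [
    6,
    8
   ],
   [
    7,
    2
   ],
   [
    7,
    3
   ],
   [
    7,
    4
   ],
   [
    7,
    5
   ],
   [
    7,
    6
   ],
   [
    7,
    7
   ],
   [
    8,
    3
   ],
   [
    8,
    4
   ],
   [
    8,
    5
   ],
   [
    8,
    6
   ]
  ],
  "blind_spot": [
   [
    4,
    7
   ],
   [
    5,
    7
   ]
  ]
 },
 "30-2": {
  "spacing_deg": 6,
  "active": [
   [
    0,
    3
   ],
   [
    0,
    4
   ],
   [
    0,
    5
   ],
   [
    0,
    6
   ],
   [
    1,
    2
   ],
   [
    1,
    3
   ],
   [
    1,
    4
   ],
   [
    1,
    5
   ],
   [
    1,
    6
   ],
   [
    1,
    7
   ],
   [
    2,
    1
   ],
   [
    2,
    2
   ],
   [
    2,
    3
   ],
   [
    2,
    4
   ],
   [
    2,
    5
   ],
   [
    2,
    6
   ],
   [
    2,
    7
   ],
   [
    2,
    8
   ],
   [
    3,
    0
   ],
   [
    3,
    1
   ],
   [
    3,
    2
   ],
   [
    3,
    3
   ],
   [
    3,
    4
   ],
   [
    3,
    5
   ],
   [
    3,
    6
   ],
   [
    3,
    7
   ],
   [
    3,
    8
   ],
   [
    3,
    9
   ],
   [
    4,
    0
   ],
   [
    4,
    1
   ],
   [
    4,
    2
   ],
   [
    4,
    3
   ],
   [
    4,
    4
   ],
   [
    4,
    5
   ],
   [
    4,
    6
   ],
   [
    4,
    8
   ],
   [
    4,
    9
   ],
   [
    5,
    0
   ],
   [
    5,
    1
   ],
   [
    5,
    2
   ],
   [
    5,
    3
   ],
   [
    5,
    4
   ],
   [
    5,
    5
   ],
   [
    5,
    6
   ],
   [
    5,
    8
   ],
   [
    5,
    9
   ],
   [
    6,
    0
   ],
   [
    6,
    1
   ],
   [
    6,
    2
   ],
   [
    6,
    3
   ],
   [
    6,
    4
   ],
   [
    6,
    5
   ],
   [
    6,
    6
   ],
   [
    6,
    7
   ],
   [
    6,
    8
   ],
   [
    6,
    9
   ],
   [
    7,
    1
   ],
   [
    7,
    2
   ],
   [
    7,
    3
   ],
   [
    7,
    4
   ],
   [
    7,
    5
   ],
   [
    7,
    6
   ],
   [
    7,
    7
   ],
   [
    7,
    8
   ],
   [
    8,
    2
   ],
   [
    8,
    3
   ],
   [
    8,
    4
   ],
   [
    8,
    5
   ],
   [
    8,
    6
   ],
   [
    8,
    7
   ],
   [
    9,
    3
   ],
   [
    9,
    4
   ],
   [
    9,
    5
   ],
   [
    9,
    6
   ]
  ],
  "blind_spot": [
   [
    4,
    7
   ],
   [
    5,
    7
   ]
  ]
 },
 "10-2": {
  "spacing_deg": 2,
  "active": [
   [
    0,
    4
   ],
   [
    0,
    5
   ],
   [
    1,
    2
   ],
   [
    1,
    3
   ],
   [
    1,
    4
   ],
   [
    1,
    5
   ],
   [
    1,
    6
   ],
   [
    1,
    7
   ],
   [
    2,
    1
   ],
   [
    2,
    2
   ],
   [
    2,
    3
   ],
   [
    2,
    4
   ],
   [
    2,
    5
   ],
   [
    2,
    6
   ],
   [
    2,
    7
   ],
   [
    2,
    8
   ],
   [
    3,
    1
   ],
   [
    3,
    2
   ],
   [
    3,
    3
   ],
   [
    3,
    4
   ],
   [
    3,
    5
   ],
   [
    3,
    6
   ],
   [
    3,
    7
   ],
   [
    3,
    8
   ],
   [
    4,
    0
   ],
   [
    4,
    1
   ],
   [
    4,
    2
   ],
   [
    4,
    3
   ],
   [
    4,
    4
   ],
   [
    4,
    5
   ],
   [
    4,
    6
   ],
   [
    4,
    7
   ],
   [
    4,
    8
   ],
   [
    4,
    9
   ],
   [
    5,
    0
   ],
   [
    5,
    1
   ],
   [
    5,
    2
   ],
   [
    5,
    3
   ],
   [
    5,
    4
   ],
   [
    5,
    5
   ],
   [
    5,
    6
   ],
   [
    5,
    7
   ],
   [
    5,
    8
   ],
   [
    5,
    9
   ],
   [
    6,
    1
   ],
   [
    6,
    2
   ],
   [
    6,
    3
   ],
   [
    6,
    4
   ],
   [
    6,
    5
   ],
   [
    6,
    6
   ],
   [
    6,
    7
   ],
   [
    6,
    8
   ],
   [
    7,
    1
   ],
   [
    7,
    2
   ],
   [
    7,
    3
   ],
   [
    7,
    4
   ],
   [
    7,
    5
   ],
   [
    7,
    6
   ],
   [
    7,
    7
   ],
   [
    7,
    8
   ],
   [
    8,
    2
   ],
   [
    8,
    3
   ],
   [
    8,
    4
   ],
   [
    8,
    5
   ],
   [
    8,
    6
   ],
   [
    8,
    7
   ],
   [
    9,
    4
   ],
   [
    9,
    5
   ]
  ],
  "blind_spot": []
 }
}
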
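{
 "ev": {
  "expectancies": [
   [
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0
   ],
   [
    50.0,
    50.0,
    25.125,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0
   ],
   [
    50.0,
    50.0,
    25.125,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    24.8
   ]
  ],
  "probs": [
   [
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1
   ],
   [
    0.11111111111091683,
    0.11111111111091683,
    1.748566900759487e-12,
    0.11111111111091683,
    0.11111111111091683,
    0.11111111111091683,
    0.11111111111091683,
    0.11111111111091683,
    0.11111111111091683,
    0.11111111111091683
   ],
   [
    0.12499999999957645,
    0.12499999999957645,
    1.967137763351197e-12,
    0.12499999999957645,
    0.12499999999957645,
    0.12499999999957645,
    0.12499999999957645,
    0.12499999999957645,
    0.12499999999957645,
    1.4213108424035263e-12
   ]
  ],
  "chosen": [
   3,
   10,
   5
  ]
 },
 "pvl": {
  "expectancies": [
   [
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0
   ],
   [
    25.0,
    25.0,
    25.707106781186546,
    25.0,
    25.0,
    25.0,
    25.0,
    25.0,
    25.0,
    25.0
   ],
   [
    12.5,
    12.5,
    12.853553390593273,
    12.5,
    12.5,
    12.5,
    12.5,
    12.5,
    12.5,
    10.711145618000169
   ]
  ],
  "probs": [
   [
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1
   ],
   [
    0.07625874372215055,
    0.07625874372215055,
    0.31367130650064506,
    0.07625874372215055,
    0.07625874372215055,
    0.07625874372215055,
    0.07625874372215055,
    0.07625874372215055,
    0.07625874372215055,
    0.07625874372215055
   ],
   [
    0.09944257837656752,
    0.09944257837656752,
    0.2016809830191693,
    0.09944257837656752,
    0.09944257837656752,
    0.09944257837656752,
    0.09944257837656752,
    0.09944257837656752,
    0.09944257837656752,
    0.002778389968290426
   ]
  ],
  "chosen": [
   3,
   10,
   4
  ]
 },
 "evpu": {
  "expectancies": [
   [
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0
   ],
   [
    50.0,
    50.0,
    25.353553390593273,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0
   ],
   [
    50.0,
    50.0,
    25.353553390593273,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    24.105572809000083
   ]
  ],
  "probs": [
   [
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1
   ],
   [
    0.11102190327465188,
    0.11102190327465188,
    0.0008028705281331555,
    0.11102190327465188,
    0.11102190327465188,
    0.11102190327465188,
    0.11102190327465188,
    0.11102190327465188,
    0.11102190327465188,
    0.11102190327465188
   ],
   [
    0.12498378504693591,
    0.12498378504693591,
    7.68615157161956e-05,
    0.12498378504693591,
    0.12498378504693591,
    0.12498378504693591,
    0.12498378504693591,
    0.12498378504693591,
    0.12498378504693591,
    5.2858108796567344e-05
   ]
  ],
  "chosen": [
   3,
   10,
   5
  ]
 },
 "pvl2": {
  "expectancies": [
   [
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0,
    50.0
   ],
   [
    25.0,
    25.0,
    24.585786437626904,
    25.0,
    25.0,
    25.0,
    25.0,
    25.0,
    25.0,
    25.0
   ],
   [
    12.5,
    12.5,
    12.292893218813452,
    12.5,
    12.5,
    12.5,
    12.5,
    12.5,
    12.5,
    10.947213595499958
   ]
  ],
  "probs": [
   [
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1,
    0.1
   ],
   [
    0.10596884709031822,
    0.10596884709031822,
    0.04628037618713598,
    0.10596884709031822,
    0.10596884709031822,
    0.10596884709031822,
    0.10596884709031822,
    0.10596884709031822,
    0.10596884709031822,
    0.10596884709031822
   ],
   [
    0.11486781644438308,
    0.11486781644438308,
    0.07591152236347092,
    0.11486781644438308,
    0.11486781644438308,
    0.11486781644438308,
    0.11486781644438308,
    0.11486781644438308,
    0.11486781644438308,
    0.005145946081464516
   ]
  ],
  "chosen": [
   3,
   10,
   5
  ]
 }
}
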
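cyp_label,pdb_id,crystal_volume_A3,residue_numbers
1A2,2HI4,512,117 118 122 124 125 223 226 227 256 260 312 313 316 317 320 321 382 386 497 498 900
2D6,2F9Q,1019,106 110 112 120 121 175 179 209 210 213 214 216 217 220 244 248 297 300 301 304 305 307 308 309 311 312 370 373 374 482 483 484 486 487 600
3A4,1TQN,2206,50 53 57 76 78 79 105 106 107 108 109 111 115 119 120 121 122 125 212 213 215 216 220 221 223 224 227 230 234 241 301 304 305 308 309 312 369 370 371 372 373 374 481 482 483 484 508
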
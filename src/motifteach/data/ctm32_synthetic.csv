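string,ctm_bits
00,2.434154
01,2.434154
10,2.434154
11,2.434154
000,5.108246
001,5.172760
010,5.130553
011,5.172760
100,5.172760
101,5.130553
110,5.172760
111,5.108246
0000,8.795575
0001,9.076911
0010,8.918337
0011,9.029443
0100,8.918337
0101,9.146796
0110,9.033031
0111,9.076911
1000,9.076911
1001,9.033031
1010,9.146796
1011,8.918337
1100,9.029443
1101,8.918337
1110,9.076911
1111,8.795575
00000,12.889316
00001,13.599547
00010,13.150040
00011,13.710105
00100,14.662388
00101,13.895110
00110,14.637893
00111,13.710105
01000,13.150040
01001,13.852212
01010,13.267250
01011,13.895110
01100,14.637893
01101,13.852212
01110,14.957395
01111,13.599547
10000,13.599547
10001,14.957395
10010,13.852212
10011,14.637893
10100,13.895110
10101,13.267250
10110,13.852212
10111,13.150040
11000,13.710105
11001,14.637893
11010,13.895110
11011,14.662388
11100,13.710105
11101,13.150040
11110,13.599547
11111,12.889316
000000,17.097325
000001,17.124292
000010,17.994232
000011,17.392781
000100,18.945322
000101,19.530284
000110,18.151773
000111,19.852212
001000,18.945322
001001,17.642759
001010,19.267250
001011,19.530284
001100,20.267250
001101,18.852212
001110,21.267250
001111,17.392781
010000,17.994232
010001,18.764750
010010,19.530284
010011,18.852212
010100,19.267250
010101,19.267250
010110,18.097325
010111,19.530284
011000,18.151773
011001,17.267250
011010,18.097325
011011,17.642759
011100,21.267250
011101,18.764750
011110,21.852212
011111,17.124292
100000,17.124292
100001,21.852212
100010,18.764750
100011,21.267250
100100,17.642759
100101,18.097325
100110,17.267250
100111,18.151773
101000,19.530284
101001,18.097325
101010,19.267250
101011,19.267250
101100,18.852212
101101,19.530284
101110,18.764750
101111,17.994232
110000,17.392781
110001,21.267250
110010,18.852212
110011,20.267250
110100,19.530284
110101,19.267250
110110,17.642759
110111,18.945322
111000,19.852212
111001,18.151773
111010,19.530284
111011,18.945322
111100,17.392781
111101,17.994232
111110,17.124292
111111,17.097325
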
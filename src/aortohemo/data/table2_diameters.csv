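# Reference validation cohort: aortic lumen diameters (mm) at three locations,
# reconstructed from MDCTA-derived models vs measured on the images.
case,location,reconstructed_mm,measured_mm
1,AscAo,11.2,11.0
1,AI,8.9,8.8
1,DAo,8.1,8.0
2,AscAo,20.0,20.4
2,AI,13.8,13.1
2,DAo,11.5,11.7
3,AscAo,25.8,25.0
3,AI,19.3,19.0
3,DAo,16.1,15.0
4,AscAo,16.2,16.5
4,AI,10.6,11.0
4,DAo,9.1,9.7
5,AscAo,28.9,29.5
5,AI,17.4,17.5
5,DAo,14.5,14.5
6,AscAo,15.2,15.5
6,AI,10.4,11.0
6,DAo,9.1,9.4
7,AscAo,21.2,21.5
7,AI,13.0,13.2
7,DAo,11.8,11.4
8,AscAo,17.9,18.5
8,AI,11.3,11.0
8,DAo,9.8,10.0
9,AscAo,17.7,18.2
9,AI,12.8,13.0
9,DAo,12.6,12.0
10,AscAo,11.7,12.0
10,AI,8.2,8.4
10,DAo,8.0,7.8
11,AscAo,19.4,20.5
11,AI,10.8,11.0
11,DAo,10.0,10.0
12,AscAo,17.2,17.4
12,AI,12.8,12.0
12,DAo,11.4,11.5
13,AscAo,17.1,17.0
13,AI,14.2,14.5
13,DAo,12.3,12.0
14,AscAo,21.0,21.4
14,AI,16.4,16.7
14,DAo,15.3,16.0
15,AscAo,18.0,18.4
15,AI,9.7,10.7
15,DAo,8.9,8.4
16,AscAo,35.0,35.0
16,AI,13.3,13.5
16,DAo,10.0,10.0
17,AscAo,11.1,11.0
17,AI,7.8,6.9
17,DAo,7.0,7.7
18,AscAo,22.3,22.5
18,AI,15.4,15.5
18,DAo,14.1,14.0
19,AscAo,26.7,26.5
19,AI,13.4,12.8
19,DAo,10.7,10.3
20,AscAo,23.0,23.0
20,AI,13.5,13.2
20,DAo,11.0,10.2
21,AscAo,26.1,26.4
21,AI,17.2,17.4
21,DAo,16.0,15.4
22,AscAo,13.0,12.5
22,AI,6.6,6.7
22,DAo,8.3,8.7
23,AscAo,11.6,11.0
23,AI,5.3,5.5
23,DAo,8.4,8.0
24,AscAo,17.7,17.3
24,AI,11.8,11.5
24,DAo,9.7,9.2
25,AscAo,16.2,15.6
25,AI,10.1,9.7
25,DAo,8.6,8.2
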
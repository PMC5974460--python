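advice -0.2065 0.4287 -0.1902 -0.1323 0.0051 0.5363 0.6026 -0.1892
anxiety 0.1175 -0.3887 -0.1678 -0.6258 -0.4491 -0.5410 -0.7937 1.0125
anyone 0.4014 -1.1968 -0.3058 -0.3562 0.1102 0.2435 -0.3425 -0.6737
biopsy -0.2609 0.8498 0.4278 -0.9557 -0.3225 0.2977 0.1883 0.2285
book 0.4050 0.1728 0.8060 -0.4413 0.5064 -0.2241 -1.1231 0.5371
can 0.0008 0.5489 -0.7997 -0.1550 0.2595 -1.3729 0.2462 -0.2280
chemo -0.9726 -0.0414 0.6018 0.5038 0.4043 0.3687 1.0610 -0.3990
concerned 0.1801 -0.5141 0.2483 -0.7351 -0.1341 -0.3274 -0.8306 0.0586
could -0.1130 -0.3410 -0.5575 0.0379 -0.1302 0.3273 0.0935 0.9775
curious -0.0319 0.0638 -0.1765 0.2767 -0.4470 0.1260 -0.3829 -0.6749
daughter 0.2684 0.7524 0.6742 -0.1904 0.8368 -0.6764 0.4836 -0.9820
depressed -0.0204 -0.6937 0.7416 -0.6742 0.3845 -0.5327 0.2139 0.2499
diet -1.1800 0.2070 0.1629 0.3827 -0.5384 0.7423 -0.0903 0.6688
do 0.0318 0.1775 0.2475 -0.6249 0.0290 0.3916 0.6493 0.8905
else 0.3014 0.2506 0.0699 0.3633 0.1216 0.1421 0.3082 0.1624
exercise -0.1147 0.5392 0.1364 -0.2526 -0.0128 -0.2140 -0.1844 -0.1269
family -0.2423 0.1520 -0.3483 0.1276 0.5975 0.2476 -0.6527 0.3281
feeling 0.8457 0.7224 0.1733 -0.4533 0.1517 -0.2051 -0.8223 -0.2044
going 0.6001 0.2856 -0.0210 0.2876 -0.6555 -0.3090 0.5995 -0.1147
good 0.1838 -0.3606 0.3211 0.2503 -0.2323 0.2161 -0.8965 1.5766
have -0.1148 -0.1512 -1.0339 -1.0722 0.2713 0.3088 -0.1477 -0.0845
help -0.7587 0.7082 -0.9271 -0.5319 -0.0850 -0.0533 -0.3013 -0.1443
home -0.5774 -0.6183 0.1916 0.5021 0.4114 -0.5834 -0.1396 -0.1397
how -0.1365 0.2013 0.1968 0.4415 0.2705 0.2063 -0.3364 -0.2114
husband 0.6130 0.1487 -0.1418 -0.0364 -0.1898 -0.0678 -0.6001 -0.2543
i 0.2278 0.5518 -0.0639 -0.2337 0.1045 -0.0080 -0.0887 -0.2808
insurance -0.3885 0.4264 -0.1915 -0.5026 -0.2385 -0.2568 0.1297 -0.8618
it 0.2187 -0.2105 -0.1465 -0.4536 0.1167 -0.7125 0.3205 -0.0685
know 0.1711 -0.4318 -0.1868 0.1177 -0.0272 0.5019 0.1200 0.2256
long -1.4436 -0.4894 1.1774 -0.2127 -0.0902 0.2641 -0.7835 0.5030
mastectomy -0.2912 -0.1377 -0.1318 -0.2031 0.1071 0.4073 -0.2497 -0.1474
month 0.7535 -0.0669 -0.1151 -0.1273 0.0578 -0.7041 0.4126 0.3789
nausea 0.4135 0.0806 0.1130 0.3416 -0.5943 -0.8053 -0.3538 0.0296
pain -0.0844 -0.5089 -0.5449 -0.0100 -0.0699 -0.6057 0.6595 0.7697
question -0.0280 -0.3688 0.0413 -0.0045 0.2870 0.6052 -1.0395 -0.0020
radiation -0.1339 -0.8409 -0.1513 -0.3011 -0.1191 0.3693 -0.3150 -0.3163
scared -0.1008 0.0617 0.5635 0.0498 -0.0693 0.5837 -0.5764 0.2882
should -0.0460 0.3201 0.3529 -0.0558 0.3134 -0.4929 -0.3372 -0.5872
sore 0.4978 0.7986 1.1541 -0.0764 -0.7023 0.3370 0.1305 0.0010
started 0.7105 -0.1375 -1.0930 -0.1081 0.0059 -0.1435 0.0448 -0.3073
swelling -1.0117 -0.4231 -1.2649 0.2799 -0.0857 -0.3269 0.3100 0.5647
taxol 0.3502 -0.2116 -0.8827 -1.0031 -0.2373 -0.9818 -0.9707 -0.0717
that 0.4556 -0.8952 0.1722 0.2656 0.0008 0.7738 -0.7141 0.0122
thing -0.1562 -0.0781 -0.9678 -0.0522 -0.3376 -0.1518 -0.5761 -0.0535
this -1.3569 0.2540 0.2533 -0.5007 -0.1414 -0.4423 0.9227 0.2979
tired 0.3346 0.2531 0.4972 -1.4604 -0.0111 -0.1434 0.4332 0.1090
today -0.3526 0.1446 -0.0497 -0.7596 -0.0809 -0.4199 -0.3650 0.1681
tumor 0.0932 -0.1147 0.6049 0.4362 0.9980 -0.2458 -1.1183 0.2275
vitamins 1.1926 -0.2785 0.9487 -0.2905 0.1262 -0.3577 -0.3017 -0.3467
website 0.0877 0.0555 -0.0495 -0.8105 -0.8706 0.4149 0.9054 -0.1344
week 0.4962 -0.0334 0.3928 0.6562 -0.6972 -1.0098 0.2960 -0.8720
what -0.0867 -0.0557 -0.4427 -0.0944 -0.3967 -0.4364 0.5524 0.9504
when 0.5206 0.4053 -0.7330 0.6332 0.0174 0.5933 -0.8084 -0.1330
where 0.6823 -0.1701 -0.1524 0.2727 0.0291 0.5192 -0.8026 0.8726
why 0.0254 0.4173 1.0046 -0.5753 -0.4781 -0.8786 -0.7742 0.0789
wondering 0.4009 -0.2761 0.6309 -0.0119 0.0661 -0.3571 0.0280 -0.2503
would -0.0079 0.0254 -0.6116 0.0274 0.5925 0.1314 -0.1852 0.3935
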
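-0.65925948706689863 -0.18497589256127023 0.92248359609569441 0.99630732205631245 0.56900636950808337 0.85111812330720582 0.30029929659633725 -0.16331027505001461 -0.85305024532285811 -0.53469450952323549 -0.92714021424503601 -0.82661725123520169 -0.50388589277304741 0.64829512954706126 0.24592161744243615 -0.092361401694201054 0.84509023951257545 0.84766593249536681 0.58555306237252047 -0.65983051270900672 0.27406965472173411 -0.113258058097492 -0.50737799291751073 -0.66728843461220377 -0.28911955404082101 0.5222456399913965 0.56144006496899146 0.24182542961526063 0.077473672430454749 -0.17085937384762939 -0.31270602785444135 0.17399341329137566
0.75191532825904617 -0.98134889630648625 -0.3818406988537032 0.057483115510065359 0.81683442281663021 0.49755823825522044 -0.92823787240888556 0.96157024792918167 -0.45280418763470032 -0.76316543740687337 -0.016042809427397494 0.41796339767442015 0.76536139460391384 -0.62899909258244846 0.86608049856708691 -0.87686123705692764 -0.23124076256249909 0.19784765850940131 0.59260248339185906 -0.37039932888838523 -0.7045154728146118 0.73068204557841576 0.46555531921540544 0.067658265548832669 -0.59316545092333128 -0.30637505008346466 0.15390376126277838 0.50049636015112497 -0.40101430961749307 0.29871726240136465 -0.14120528494166187 0.02441969014939803
0.00051753394126578681 0.05232841378450824 0.056759982675043397 0.063776260851792027 0.094938280798913366 0.16743279165797026 0.21953310613565991 0.22070888600258204 0.2593716380313984 0.36287779848494767 0.37437100768535064 0.37684282952553849 0.40040097741421771 0.42903795465671224 0.435232269111887 0.47178781504409051 0.48202717434818115 0.49225884543510989 0.5531273884232859 0.65377980364737698 0.65463254801874426 0.67325801929522322 0.72513848129391145 0.74171996341996793 0.75137516015779882 0.79586042758534692 0.8130797536015667 0.83127844617003632 0.9127898737180119 0.93892229258433857 0.93929548473738633 0.98444399071974831
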
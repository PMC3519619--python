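# wavelength_nm	epsilon
450.0	1.23188317e-01
451.0	1.23129873e-01
452.0	1.22954701e-01
453.0	1.22663316e-01
454.0	1.22256569e-01
455.0	1.21735648e-01
456.0	1.21102069e-01
457.0	1.20357670e-01
458.0	1.19504604e-01
459.0	1.18545325e-01
460.0	1.17482578e-01
461.0	1.16319389e-01
462.0	1.15059046e-01
463.0	1.13705087e-01
464.0	1.12261282e-01
465.0	1.10731618e-01
466.0	1.09120280e-01
467.0	1.07431632e-01
468.0	1.05670198e-01
469.0	1.03840644e-01
470.0	1.01947760e-01
471.0	9.99964351e-02
472.0	9.79916429e-02
473.0	9.59384209e-02
474.0	9.38418514e-02
475.0	9.17070434e-02
476.0	8.95391151e-02
477.0	8.73431770e-02
478.0	8.51243162e-02
479.0	8.28875818e-02
480.0	8.06379709e-02
481.0	7.83804173e-02
482.0	7.61197802e-02
483.0	7.38608350e-02
484.0	7.16082664e-02
485.0	6.93666622e-02
486.0	6.71405096e-02
487.0	6.49341928e-02
488.0	6.27519932e-02
489.0	6.05980905e-02
490.0	5.84765664e-02
491.0	5.63914098e-02
492.0	5.43465237e-02
493.0	5.23457336e-02
494.0	5.03927974e-02
495.0	4.84914167e-02
496.0	4.66452487e-02
497.0	4.48579194e-02
498.0	4.31330366e-02
499.0	4.14742034e-02
500.0	3.98850314e-02
501.0	3.83691529e-02
502.0	3.69302320e-02
503.0	3.55719740e-02
504.0	3.42981326e-02
505.0	3.31125140e-02
506.0	3.20189787e-02
507.0	3.10214378e-02
508.0	3.01238465e-02
509.0	2.93301920e-02
510.0	2.86444757e-02
511.0	2.80706908e-02
512.0	2.76127928e-02
513.0	2.72746640e-02
514.0	2.70600724e-02
515.0	2.69726232e-02
516.0	2.70157046e-02
517.0	2.71924278e-02
518.0	2.75055614e-02
519.0	2.79574614e-02
520.0	2.85499964e-02
521.0	2.92844708e-02
522.0	3.01615460e-02
523.0	3.11811605e-02
524.0	3.23424516e-02
525.0	3.36436800e-02
526.0	3.50821580e-02
527.0	3.66541840e-02
528.0	3.83549856e-02
529.0	4.01786711e-02
530.0	4.21181940e-02
531.0	4.41653296e-02
532.0	4.63106665e-02
533.0	4.85436147e-02
534.0	5.08524301e-02
535.0	5.32242579e-02
536.0	5.56451937e-02
537.0	5.81003646e-02
538.0	6.05740277e-02
539.0	6.30496876e-02
540.0	6.55102311e-02
541.0	6.79380771e-02
542.0	7.03153415e-02
543.0	7.26240134e-02
544.0	7.48461413e-02
545.0	7.69640263e-02
546.0	7.89604190e-02
547.0	8.08187170e-02
548.0	8.25231602e-02
549.0	8.40590202e-02
550.0	8.54127799e-02
551.0	8.65723016e-02
552.0	8.75269788e-02
553.0	8.82678698e-02
554.0	8.87878107e-02
555.0	8.90815051e-02
556.0	8.91455893e-02
557.0	8.89786712e-02
558.0	8.85813427e-02
559.0	8.79561647e-02
560.0	8.71076260e-02
561.0	8.60420750e-02
562.0	8.47676285e-02
563.0	8.32940556e-02
564.0	8.16326423e-02
565.0	7.97960369e-02
566.0	7.77980807e-02
567.0	7.56536255e-02
568.0	7.33783433e-02
569.0	7.09885286e-02
570.0	6.85009000e-02
571.0	6.59324016e-02
572.0	6.33000088e-02
573.0	6.06205416e-02
574.0	5.79104874e-02
575.0	5.51858360e-02
576.0	5.24619295e-02
577.0	4.97533277e-02
578.0	4.70736918e-02
579.0	4.44356859e-02
580.0	4.18508977e-02
581.0	3.93297788e-02
582.0	3.68816031e-02
583.0	3.45144450e-02
584.0	3.22351735e-02
585.0	3.00494644e-02
586.0	2.79618264e-02
587.0	2.59756416e-02
588.0	2.40932173e-02
589.0	2.23158484e-02
590.0	2.06438878e-02
591.0	1.90768235e-02
592.0	1.76133605e-02
593.0	1.62515052e-02
594.0	1.49886520e-02
595.0	1.38216693e-02
596.0	1.27469838e-02
597.0	1.17606627e-02
598.0	1.08584922e-02
599.0	1.00360511e-02
600.0	9.28877934e-03
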